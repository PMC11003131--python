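import numpy as np
import pytest

from cgstack import core_io, mapping


@pytest.fixture(scope="session")
def thermo():
    from cgstack.boltzmann import ThermoState

    return ThermoState()


@pytest.fixture(scope="session")
def chain_system():
    """Three-bead chain with two bonds and one angle, plus its ground-truth
    harmonic force field and a sensible starting frame."""
    beads = [
        core_io.BeadDefinition(bead_name=f"B{i}", member_atoms=(i,), bead_type="T")
        for i in range(3)
    ]
    topo = core_io.CGTopology(
        beads=beads, bond_terms=((0, 1), (1, 2)), angle_terms=((0, 1, 2),)
    )
    ff = core_io.ForceField(
        bond_params={
            (0, 1): core_io.HarmonicParams(0.47, 1250.0),
            (1, 2): core_io.HarmonicParams(0.40, 2000.0),
        },
        angle_params={(0, 1, 2): core_io.HarmonicParams(120.0, 25.0)},
    )
    start = mapping.CGFrame(
        np.array([[0.0, 0.0, 0.0], [0.47, 0.0, 0.0], [0.27, 0.35, 0.0]])
    )
    masses = np.array([72.0, 72.0, 72.0])
    return topo, ff, start, masses


@pytest.fixture(scope="session")
def single_bond_system():
    beads = [
        core_io.BeadDefinition(bead_name=f"B{i}", member_atoms=(i,))
        for i in range(2)
    ]
    topo = core_io.CGTopology(beads=beads, bond_terms=((0, 1),))
    ff = core_io.ForceField(
        bond_params={(0, 1): core_io.HarmonicParams(0.47, 6450.0)}
    )
    start = mapping.CGFrame(np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]))
    masses = np.array([72.0, 72.0])
    return topo, ff, start, masses


@pytest.fixture
def diatomic_topology():
    """Two-atom molecular topology (C at origin-ish masses)."""
    atoms = [
        core_io.AtomRecord(name="C1", element="C", mass=12.0, molecule_id=0),
        core_io.AtomRecord(name="H1", element="H", mass=1.0, molecule_id=0),
    ]
    return core_io.MolecularTopology(molecule_name="MOL", atoms=atoms,
                                     bonds={(0, 1)})
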