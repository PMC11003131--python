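"""Structure/trajectory I/O, mapping config, parameter export."""

import numpy as np
import pytest

from cgstack import core_io
from cgstack.core_io import (
    AtomRecord,
    BeadDefinition,
    CGTopology,
    ForceField,
    Frame,
    HarmonicParams,
    Trajectory,
    export_parameters,
    import_parameters,
    load_mapping_config,
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)
from cgstack.errors import (
    ConfigError,
    MissingParameterError,
    ParseError,
    UnsupportedFeatureError,
)

PDB_TWO_ATOMS = (
    "ATOM      1  C1  MOL     1       0.000   0.000   0.000  1.00  0.00"
    "           C\n"
    "ATOM      2  C2  MOL     1       1.500   0.000   0.000  1.00  0.00"
    "           C\n"
    "END\n"
)

XYZ_THREE_FRAMES = """2
t=0
C 0.0 0.0 0.0
C 1.5 0.0 0.0
2
t=1
C 0.0 0.0 0.0
C 1.6 0.0 0.0
2
t=2
C 0.0 0.0 0.0
C 1.7 0.0 0.0
"""


class TestReadStructure:
    def test_pdb_angstrom_to_nm(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(PDB_TWO_ATOMS)
        topo, frame = read_structure(p)
        assert topo.n_atoms == 2
        assert [a.name for a in topo.atoms] == ["C1", "C2"]
        assert [a.element for a in topo.atoms] == ["C", "C"]
        np.testing.assert_allclose(
            frame.coordinates, [[0, 0, 0], [0.15, 0, 0]], atol=1e-12
        )

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ParseError):
            read_structure(p)

    def test_masses_come_from_element_table(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(PDB_TWO_ATOMS)
        topo, _ = read_structure(p)
        assert topo.atoms[0].mass == pytest.approx(12.011)

    def test_unknown_element_needs_override(self, tmp_path):
        p = tmp_path / "x.xyz"
        p.write_text("1\ncomment\nXx 0.0 0.0 0.0\n")
        with pytest.raises(ConfigError, match="unknown element"):
            read_structure(p)
        topo, _ = read_structure(p, mass_overrides={"Xx": 72.0})
        assert topo.atoms[0].mass == 72.0

    def test_malformed_pdb_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  C1  MOL     1      bad-coordinates\n")
        with pytest.raises(ParseError, match="line 1"):
            read_structure(p)

    def test_triclinic_gro_rejected(self, tmp_path):
        p = tmp_path / "tri.gro"
        p.write_text(
            "title\n    1\n    1MOL     C1    1   0.000   0.000   0.000\n"
            "   5.0   5.0   5.0   0.0   0.0   1.2   0.0   0.0   0.0\n"
        )
        with pytest.raises(UnsupportedFeatureError, match="triclinic"):
            read_structure(p)

    def test_gro_reads_nm_and_box(self, tmp_path):
        p = tmp_path / "ok.gro"
        p.write_text(
            "title\n    2\n    1MOL     C1    1   0.000   0.000   0.000\n"
            "    1MOL     C2    2   0.150   0.000   0.000\n   5.0   5.0   5.0\n"
        )
        topo, frame = read_structure(p)
        assert frame.coordinates[1, 0] == pytest.approx(0.15)
        np.testing.assert_allclose(frame.box, [5, 5, 5])


class TestReadTrajectory:
    def test_multiframe_xyz(self, tmp_path):
        p = tmp_path / "t.xyz"
        p.write_text(XYZ_THREE_FRAMES)
        traj = read_trajectory(p)
        assert len(traj) == 3
        assert traj.atom_count == 2
        assert traj.frames[2].coordinates[1, 0] == pytest.approx(0.17)
        assert [f.time for f in traj] == [0.0, 1.0, 2.0]

    def test_single_frame(self, tmp_path):
        p = tmp_path / "t.xyz"
        p.write_text("1\nc\nC 0.0 0.0 0.0\n")
        assert len(read_trajectory(p)) == 1

    def test_corrupt_atom_line_names_frame_and_line(self, tmp_path):
        p = tmp_path / "t.xyz"
        p.write_text("2\nt=0\nC 0 0 0\nC 1 0 0\n2\nt=1\nC 0 0 0\nC oops 0 0\n")
        with pytest.raises(ParseError, match="frame 1.*line 8"):
            read_trajectory(p)

    def test_deviating_atom_count_names_frame(self, tmp_path):
        p = tmp_path / "t.xyz"
        p.write_text("2\nt=0\nC 0 0 0\nC 1 0 0\n1\nt=1\nC 0 0 0\n")
        with pytest.raises(ParseError, match="frame 1"):
            read_trajectory(p)


class TestRoundTrips:
    def test_xyz_trajectory_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = [
            Frame(rng.uniform(0, 2, (4, 3)), box=np.array([5.0, 5.0, 5.0]),
                  time=float(k))
            for k in range(3)
        ]
        traj = Trajectory(frames)
        p = tmp_path / "rt.xyz"
        write_trajectory(p, traj, ["C", "N", "O", "S"])
        back = read_trajectory(p)
        assert len(back) == 3
        for a, b in zip(traj, back):
            # XYZ stores Angstrom with 6 decimals
            np.testing.assert_allclose(a.coordinates, b.coordinates, atol=1e-6)
            np.testing.assert_allclose(a.box, b.box, atol=1e-6)
            assert a.time == pytest.approx(b.time)

    def test_pdb_roundtrip_within_milli_angstrom(self, tmp_path, diatomic_topology):
        frame = Frame(np.array([[0.1234567, 0.0, 0.2], [0.3, 0.4, 0.5]]))
        p = tmp_path / "rt.pdb"
        write_structure(p, diatomic_topology, frame)
        _, back = read_structure(p)
        # PDB stores Angstrom with 3 decimals -> 1e-3 A = 1e-4 nm
        np.testing.assert_allclose(back.coordinates, frame.coordinates,
                                   atol=1.0001e-4)

    def test_gro_trajectory_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = [Frame(rng.uniform(0, 2, (3, 3)), time=float(k)) for k in range(2)]
        p = tmp_path / "rt.gro"
        write_trajectory(p, Trajectory(frames), ["C", "C", "C"], format="gro")
        back = read_trajectory(p, format="gro")
        for a, b in zip(frames, back):
            np.testing.assert_allclose(a.coordinates, b.coordinates, atol=5.1e-4)

    def test_mdtraj_reads_our_pdb_identically(self, tmp_path, diatomic_topology):
        """Independent parser oracle for the PDB writer/reader pair."""
        mdtraj = pytest.importorskip("mdtraj")
        frame = Frame(np.array([[0.111, 0.222, 0.333], [0.444, 0.555, 0.666]]))
        p = tmp_path / "oracle.pdb"
        write_structure(p, diatomic_topology, frame)
        ours = read_structure(p)[1].coordinates
        theirs = mdtraj.load(str(p)).xyz[0]  # mdtraj reports nm
        np.testing.assert_allclose(ours, theirs, atol=1e-4)


MAPPING_OK = """
molecule: TOY
atoms: [C1, C2, C3, N1, N2, N3]
beads:
  - name: B1
    type: P1
    atoms: [C1, C2, C3]
  - name: B2
    atoms: [N1, N2, N3]
    weighting: geometric
bonds:
  - [B1, B2]
"""


class TestMappingConfig:
    def test_parses_beads_and_terms(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text(MAPPING_OK)
        scheme, topo = load_mapping_config(p)
        assert len(scheme) == 2
        assert topo.bond_terms == ((0, 1),)
        assert topo.angle_terms == ()
        assert scheme[0].member_atoms == (0, 1, 2)
        assert scheme[0].bead_type == "P1"
        assert scheme[1].bead_type == "B2"  # defaults to the name

    def test_weighting_defaults_to_mass(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text(MAPPING_OK)
        scheme, _ = load_mapping_config(p)
        assert scheme[0].weighting == "mass"
        assert scheme[1].weighting == "geometric"

    def test_unknown_atom_names_bead_and_atom(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text(
            "molecule: T\natoms: [C1]\nbeads:\n  - name: B3\n    atoms: [X9]\n"
        )
        with pytest.raises(ConfigError, match="B3.*X9"):
            load_mapping_config(p)

    def test_duplicate_bead_names_rejected(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text(
            "molecule: T\natoms: [C1, C2]\nbeads:\n"
            "  - name: B1\n    atoms: [C1]\n  - name: B1\n    atoms: [C2]\n"
        )
        with pytest.raises(ConfigError, match="duplicate bead name"):
            load_mapping_config(p)

    def test_term_with_undefined_bead_rejected(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text(
            "molecule: T\natoms: [C1, C2, C3]\nbeads:\n"
            "  - name: B1\n    atoms: [C1]\n  - name: B2\n    atoms: [C2]\n"
            "angles:\n  - [B1, B2, B9]\n"
        )
        with pytest.raises(ConfigError, match="B9"):
            load_mapping_config(p)

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text(MAPPING_OK + "\nextra_key: 1\n")
        with pytest.raises(ConfigError, match="unknown config keys"):
            load_mapping_config(p)


def _toy_ff_topo():
    beads = [BeadDefinition(bead_name=f"B{i}", member_atoms=(i,)) for i in range(3)]
    topo = CGTopology(beads=beads, bond_terms=((0, 1), (1, 2)),
                      angle_terms=((0, 1, 2),))
    ff = ForceField(
        bond_params={(0, 1): HarmonicParams(0.470, 1250.0),
                     (1, 2): HarmonicParams(0.35, 900.0)},
        angle_params={(0, 1, 2): HarmonicParams(120.0, 25.0)},
        pair_params={("B1", "B3"): (2.0, 0.43)},
    )
    return ff, topo


class TestParameterExport:
    def test_itp_bond_line_format(self):
        ff, topo = _toy_ff_topo()
        text = export_parameters(ff, topo, "itp")
        assert "[ bonds ]" in text
        assert "1 2 1 0.470 1250.0" in text
        assert "[ angles ]" in text
        assert "1 2 3 2 120.00 25.00" in text

    def test_structured_roundtrip_is_lossless(self):
        ff, topo = _toy_ff_topo()
        back = import_parameters(export_parameters(ff, topo, "structured"))
        assert back.cutoff == ff.cutoff
        for term in topo.bond_terms:
            assert back.bond(term) == ff.bond(term)
        for term in topo.angle_terms:
            assert back.angle(term) == ff.angle(term)
        assert back.pair_params == ff.pair_params

    def test_missing_angle_params_named(self):
        ff, topo = _toy_ff_topo()
        ff.angle_params.clear()
        with pytest.raises(MissingParameterError, match=r"\(0, 1, 2\)"):
            export_parameters(ff, topo, "itp")


class TestTypeInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="", element="C", mass=12.0),
            dict(name="C1", element="C", mass=0.0),
            dict(name="C1", element="C", mass=12.0, molecule_id=-1),
        ],
    )
    def test_atom_record_validation(self, kwargs):
        with pytest.raises(ValueError):
            AtomRecord(**kwargs)

    def test_frame_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Frame(np.array([[0.0, 0.0, np.nan]]))

    def test_trajectory_times_must_be_monotone(self):
        f1 = Frame(np.zeros((1, 3)), time=1.0)
        f2 = Frame(np.zeros((1, 3)), time=0.5)
        with pytest.raises(ValueError):
            Trajectory([f1, f2])

    def test_cg_topology_rejects_self_bond_and_bad_angle(self):
        beads = [BeadDefinition(bead_name=f"B{i}", member_atoms=(i,))
                 for i in range(3)]
        with pytest.raises(ValueError):
            CGTopology(beads=beads, bond_terms=((0, 0),))
        with pytest.raises(ValueError):
            CGTopology(beads=beads, angle_terms=((0, 1, 1),))

    def test_reference_axis_must_lie_in_core(self):
        atoms = [AtomRecord(name=f"C{i}", element="C", mass=12.0)
                 for i in range(4)]
        with pytest.raises(ValueError):
            core_io.MolecularTopology(
                molecule_name="M", atoms=atoms, core_atoms=(0, 1, 2),
                reference_axis=(0, 3),
            )
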