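"""Domain types, structure/trajectory I/O, mapping config, parameter export.

Supported text formats: PDB (ATOM/HETATM, Angstrom), GRO (nm, possibly
multi-frame), multi-frame XYZ (Angstrom).  All coordinates are converted to
nm on read.  Only orthorhombic boxes are supported; triclinic input raises
:class:`~cgstack.errors.UnsupportedFeatureError`.

The mapping-scheme configuration and the structured force-field
serialization are documented in ``docs/formats.md``; the field names used
there are the ones parsed here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from cgstack.constants import ANGSTROM_TO_NM, DEFAULT_CUTOFF
from cgstack.errors import (
    ConfigError,
    MissingParameterError,
    ParseError,
    UnsupportedFeatureError,
)

# ---------------------------------------------------------------------------
# element masses (amu); config files may override per atom
# ---------------------------------------------------------------------------

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
    "BR": 79.904,
    "I": 126.904,
}


def element_mass(element: str, overrides: Optional[dict[str, float]] = None) -> float:
    """Mass for an element symbol, honouring explicit overrides.

    Raises :class:`ConfigError` for unknown elements without an override.
    """
    if overrides and element in overrides:
        return float(overrides[element])
    key = element.strip().upper()
    if overrides and key in overrides:
        return float(overrides[key])
    try:
        return ELEMENT_MASSES[key]
    except KeyError:
        raise ConfigError(
            f"unknown element {element!r}; supply a mass override"
        ) from None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the atomistic description."""

    name: str
    element: str
    mass: float
    molecule_id: int = 0

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not self.mass > 0:
            raise ValueError(f"atom mass must be > 0, got {self.mass}")
        if self.molecule_id < 0:
            raise ValueError("molecule_id must be >= 0")


@dataclass
class MolecularTopology:
    """Atoms, bonds and the planar-core annotation of one molecule type.

    ``core_atoms`` marks the flat aromatic core whose best-fit plane defines
    the molecular normal in stacking analysis; ``reference_axis`` is an
    ordered atom pair whose difference vector fixes an in-plane orientation
    used to measure inter-molecular rotation angles.
    """

    molecule_name: str
    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    core_atoms: tuple[int, ...] = ()
    reference_axis: Optional[tuple[int, int]] = None

    def __post_init__(self):
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-bond ({i},{i})")
        for i in self.core_atoms:
            if not 0 <= i < n:
                raise ValueError(f"core atom {i} out of range")
        if self.reference_axis is not None:
            a, b = self.reference_axis
            if a == b:
                raise ValueError("reference_axis atoms must be distinct")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError("reference_axis atom out of range")
            if self.core_atoms and not (
                a in self.core_atoms and b in self.core_atoms
            ):
                raise ValueError("reference_axis atoms must lie in core_atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)


@dataclass
class Frame:
    """One coordinate snapshot (nm) with an optional orthorhombic box."""

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must be three orthorhombic edge lengths")
            if not np.all(self.box > 0):
                raise ValueError("box edges must be > 0")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames with a constant atom count and non-decreasing times."""

    frames: list[Frame]

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.frames[0].n_atoms
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {fr.n_atoms} atoms, expected {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")

    @property
    def atom_count(self) -> int:
        return self.frames[0].n_atoms

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class BeadDefinition:
    """One coarse-grained bead: member atoms and the averaging rule."""

    bead_name: str
    member_atoms: tuple[int, ...]
    bead_type: str = ""
    weighting: str = "mass"

    def __post_init__(self):
        if not self.member_atoms:
            raise ValueError(f"bead {self.bead_name!r} has no member atoms")
        if len(set(self.member_atoms)) != len(self.member_atoms):
            raise ValueError(f"bead {self.bead_name!r} has duplicate members")
        if self.weighting not in ("mass", "geometric"):
            raise ValueError(
                f"weighting must be 'mass' or 'geometric', got {self.weighting!r}"
            )
        if not self.bead_type:
            object.__setattr__(self, "bead_type", self.bead_name)


@dataclass
class CGTopology:
    """Bead list plus the bonded terms whose distributions are matched."""

    beads: list[BeadDefinition]
    bond_terms: tuple[tuple[int, int], ...] = ()
    angle_terms: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self):
        n = len(self.beads)
        for i, j in self.bond_terms:
            if i == j:
                raise ValueError(f"self-bond ({i},{i})")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond term ({i},{j}) out of range")
        for t in self.angle_terms:
            if len(set(t)) != 3:
                raise ValueError(f"angle term {t} must use three distinct beads")
            if not all(0 <= i < n for i in t):
                raise ValueError(f"angle term {t} out of range")

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class BondedDistribution:
    """Samples and summary of one bonded marginal (nm or degrees)."""

    term: tuple
    kind: str  # "bond" | "angle"
    samples: np.ndarray
    mean: float
    variance: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.kind not in ("bond", "angle"):
            raise ValueError("kind must be 'bond' or 'angle'")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.kind == "bond" and np.any(self.samples < 0):
            raise ValueError("bond samples must be >= 0")
        if self.kind == "angle" and (
            np.any(self.samples < 0) or np.any(self.samples > 180)
        ):
            raise ValueError("angle samples must lie in [0, 180] degrees")
        if int(self.counts.sum()) != self.samples.size:
            raise ValueError("histogram counts must sum to the sample count")

    @property
    def n(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class HarmonicParams:
    """Equilibrium value and force constant of a harmonic bonded term.

    Units: nm and kJ mol^-1 nm^-2 for bonds; degrees and kJ mol^-1 rad^-2
    for angles (ITP conventions).
    """

    equilibrium: float
    force_constant: float

    def __post_init__(self):
        if not self.force_constant > 0:
            raise ValueError("force_constant must be > 0")
        if not self.equilibrium > 0:
            raise ValueError("equilibrium must be > 0")


@dataclass
class ForceField:
    """Harmonic bonded parameters plus optional LJ pair terms and cutoff."""

    bond_params: dict[tuple[int, int], HarmonicParams] = field(default_factory=dict)
    angle_params: dict[tuple[int, int, int], HarmonicParams] = field(
        default_factory=dict
    )
    pair_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # (type_a, type_b) sorted -> (epsilon kJ/mol, sigma nm)
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")
        self.pair_params = {
            tuple(sorted(k)): tuple(map(float, v)) for k, v in self.pair_params.items()
        }

    def bond(self, term: tuple[int, int]) -> HarmonicParams:
        try:
            return self.bond_params[tuple(term)]
        except KeyError:
            try:
                return self.bond_params[tuple(reversed(term))]
            except KeyError:
                raise MissingParameterError(f"no bond parameters for term {term}") from None

    def angle(self, term: tuple[int, int, int]) -> HarmonicParams:
        try:
            return self.angle_params[tuple(term)]
        except KeyError:
            try:
                return self.angle_params[tuple(reversed(term))]
            except KeyError:
                raise MissingParameterError(
                    f"no angle parameters for term {term}"
                ) from None

    def pair(self, type_a: str, type_b: str) -> Optional[tuple[float, float]]:
        return self.pair_params.get(tuple(sorted((type_a, type_b))))

    def validate_complete(self, topology: CGTopology) -> None:
        """Raise :class:`MissingParameterError` for any unparametrized term."""
        for t in topology.bond_terms:
            self.bond(t)
        for t in topology.angle_terms:
            self.angle(t)


# ---------------------------------------------------------------------------
# structure / trajectory readers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _PDBRecord:
    name: str
    resname: str
    resid: int
    element: str
    xyz: tuple[float, float, float]  # Angstrom


def _guess_element(atom_name: str) -> str:
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in ELEMENT_MASSES and two not in ("CA",):  # CA in PDB is alpha carbon
        return two
    return stripped[0].upper()


def read_pdb_records(path) -> list[_PDBRecord]:
    """Parse ATOM/HETATM records from a PDB file (coordinates in Angstrom)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                name = line[12:16].strip()
                resname = line[17:20].strip()
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError):
                raise ParseError("malformed ATOM/HETATM record", path=path, line=lineno)
            element = line[76:78].strip() if len(line) >= 77 else ""
            if not element:
                element = _guess_element(name)
            records.append(_PDBRecord(name, resname, resid, element, (x, y, z)))
    if not records:
        raise ParseError("no ATOM/HETATM records found", path=path)
    return records


def _contiguous_ids(raw_ids: Sequence[int]) -> list[int]:
    mapping: dict[int, int] = {}
    out = []
    for r in raw_ids:
        if r not in mapping:
            mapping[r] = len(mapping)
        out.append(mapping[r])
    return out


def _read_pdb(path, mass_overrides):
    records = read_pdb_records(path)
    mol_ids = _contiguous_ids([r.resid for r in records])
    atoms = [
        AtomRecord(
            name=r.name,
            element=r.element,
            mass=element_mass(r.element, mass_overrides),
            molecule_id=m,
        )
        for r, m in zip(records, mol_ids)
    ]
    coords = np.array([r.xyz for r in records], dtype=float) * ANGSTROM_TO_NM
    name = records[0].resname or Path(path).stem
    return MolecularTopology(molecule_name=name, atoms=atoms), Frame(coords)


def _parse_gro_box(tokens, path, lineno):
    try:
        vals = [float(t) for t in tokens]
    except ValueError:
        raise ParseError("malformed box line", path=path, line=lineno)
    if len(vals) == 3:
        if all(v == 0 for v in vals):
            return None  # GRO convention for "no box"
        return np.array(vals)
    if len(vals) == 9:
        if any(abs(v) > 1e-12 for v in vals[3:]):
            raise UnsupportedFeatureError(
                f"{path}: triclinic boxes are not supported (orthorhombic only)"
            )
        return np.array(vals[:3])
    raise ParseError("box line must have 3 or 9 values", path=path, line=lineno)


def _read_gro_frames(path):
    """Yield (names, resnames, resids, coords_nm, box, time, first_lineno)."""
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip() and pos == len(lines) - 1:
            break
        title = lines[pos]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        try:
            natoms = int(lines[pos + 1])
        except (ValueError, IndexError):
            raise ParseError("expected atom count", path=path, line=pos + 2, frame=frame_idx)
        end = pos + 2 + natoms
        if end >= len(lines) + 1 or len(lines) < end + 1:
            raise ParseError(
                f"truncated frame (expected {natoms} atoms + box)",
                path=path,
                frame=frame_idx,
            )
        names, resnames, resids, coords = [], [], [], []
        for k in range(natoms):
            line = lines[pos + 2 + k]
            try:
                resids.append(int(line[0:5]))
                resnames.append(line[5:10].strip())
                names.append(line[10:15].strip())
                coords.append(
                    (float(line[20:28]), float(line[28:36]), float(line[36:44]))
                )
            except (ValueError, IndexError):
                raise ParseError(
                    "malformed GRO atom line", path=path, line=pos + 3 + k, frame=frame_idx
                )
        box = _parse_gro_box(lines[end].split(), path, end + 1)
        yield names, resnames, resids, np.array(coords), box, time
        pos = end + 1
        frame_idx += 1


def _read_gro(path, mass_overrides):
    gen = _read_gro_frames(path)
    try:
        names, resnames, resids, coords, box, time = next(gen)
    except StopIteration:
        raise ParseError("empty GRO file", path=path)
    mol_ids = _contiguous_ids(resids)
    atoms = []
    for nm, m in zip(names, mol_ids):
        el = _guess_element(nm)
        atoms.append(
            AtomRecord(name=nm, element=el, mass=element_mass(el, mass_overrides), molecule_id=m)
        )
    topo = MolecularTopology(molecule_name=resnames[0] or Path(path).stem, atoms=atoms)
    return topo, Frame(coords, box=box, time=time)


def _read_xyz_frames(path):
    """Yield (symbols, coords_A, time, box) per XYZ frame."""
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError("expected atom count", path=path, line=pos + 1, frame=frame_idx)
        if pos + 2 + natoms > len(lines):
            raise ParseError(
                f"truncated frame (expected {natoms} atom lines)",
                path=path,
                frame=frame_idx,
            )
        comment = lines[pos + 1]
        time = 0.0
        box = None
        for tok in comment.split():
            if tok.startswith("t="):
                try:
                    time = float(tok[2:])
                except ValueError:
                    pass
            if tok.startswith("box="):
                try:
                    box = np.array([float(v) for v in tok[4:].split(",")])
                except ValueError:
                    pass
        symbols, coords = [], []
        for k in range(natoms):
            parts = lines[pos + 2 + k].split()
            if len(parts) < 4:
                raise ParseError(
                    "malformed XYZ atom line", path=path, line=pos + 3 + k, frame=frame_idx
                )
            try:
                coords.append((float(parts[1]), float(parts[2]), float(parts[3])))
            except ValueError:
                raise ParseError(
                    "malformed XYZ atom line", path=path, line=pos + 3 + k, frame=frame_idx
                )
            symbols.append(parts[0])
        yield symbols, np.array(coords), time, box
        pos += 2 + natoms
        frame_idx += 1


def _read_xyz(path, mass_overrides):
    gen = _read_xyz_frames(path)
    try:
        symbols, coords, time, box = next(gen)
    except StopIteration:
        raise ParseError("empty XYZ file", path=path)
    atoms = [
        AtomRecord(name=s, element=s, mass=element_mass(s, mass_overrides), molecule_id=0)
        for s in symbols
    ]
    topo = MolecularTopology(molecule_name=Path(path).stem, atoms=atoms)
    return topo, Frame(coords * ANGSTROM_TO_NM, box=box, time=time)


_STRUCTURE_READERS = {"pdb": _read_pdb, "gro": _read_gro, "xyz": _read_xyz}


def read_structure(path, format: Optional[str] = None, mass_overrides=None):
    """Read a single-frame structure.

    Returns a ``(MolecularTopology, Frame)`` pair.  The topology is a
    skeleton: atom names, elements and table-derived masses are populated;
    bonds/core annotations are left empty for the caller to fill.
    Coordinates are converted to nm.

    Parameters
    ----------
    format : {"pdb", "gro", "xyz"}, optional
        Inferred from the file suffix when omitted.
    mass_overrides : dict, optional
        Element-symbol (or atom-name) to mass map consulted before the
        built-in element table; required for unknown elements.
    """
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt not in _STRUCTURE_READERS:
        raise ConfigError(f"unsupported structure format {fmt!r}")
    return _STRUCTURE_READERS[fmt](path, mass_overrides)


def read_trajectory(path, format: Optional[str] = None) -> Trajectory:
    """Read a multi-frame trajectory (XYZ in Angstrom, or multi-frame GRO).

    Every frame must have the same atom count; a deviating frame raises
    :class:`ParseError` naming the frame index.
    """
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    frames: list[Frame] = []
    if fmt == "xyz":
        for k, (symbols, coords, time, box) in enumerate(_read_xyz_frames(path)):
            if frames and coords.shape[0] != frames[0].n_atoms:
                raise ParseError(
                    f"atom count {coords.shape[0]} deviates from {frames[0].n_atoms}",
                    path=path,
                    frame=k,
                )
            frames.append(Frame(coords * ANGSTROM_TO_NM, box=box, time=time))
    elif fmt == "gro":
        for k, (names, resnames, resids, coords, box, time) in enumerate(
            _read_gro_frames(path)
        ):
            if frames and coords.shape[0] != frames[0].n_atoms:
                raise ParseError(
                    f"atom count {coords.shape[0]} deviates from {frames[0].n_atoms}",
                    path=path,
                    frame=k,
                )
            frames.append(Frame(coords, box=box, time=time))
    else:
        raise ConfigError(f"unsupported trajectory format {fmt!r}")
    if not frames:
        raise ParseError("no frames found", path=path)
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _pdb_atom_line(serial, name, resname, resid, xyz_A, element):
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {serial:>5d} {name_f:<4s} {resname[:3]:>3s}  {resid:>4d}    "
        f"{xyz_A[0]:8.3f}{xyz_A[1]:8.3f}{xyz_A[2]:8.3f}  1.00  0.00"
        f"          {element[:2]:>2s}\n"
    )


def write_pdb(path, coordinates_nm, names, resnames, resids, elements) -> None:
    """Write one frame as PDB (nm converted to Angstrom, 3 decimals)."""
    coords_A = np.asarray(coordinates_nm) / ANGSTROM_TO_NM
    with open(path, "w") as fh:
        for k in range(coords_A.shape[0]):
            fh.write(
                _pdb_atom_line(
                    (k % 99999) + 1, names[k], resnames[k], (resids[k] % 9999) + 1,
                    coords_A[k], elements[k],
                )
            )
        fh.write("END\n")


def _write_gro_frame(fh, names, resnames, resids, coords_nm, box, time):
    fh.write(f"written by cgstack t= {time:.4f}\n")
    fh.write(f"{len(names):5d}\n")
    for k in range(len(names)):
        fh.write(
            f"{(resids[k] % 99999) + 1:5d}{resnames[k][:5]:<5s}{names[k][:5]:>5s}"
            f"{(k % 99999) + 1:5d}"
            f"{coords_nm[k, 0]:8.3f}{coords_nm[k, 1]:8.3f}{coords_nm[k, 2]:8.3f}\n"
        )
    b = box if box is not None else np.zeros(3)
    fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


def _write_xyz_frame(fh, symbols, coords_nm, box, time):
    fh.write(f"{len(symbols)}\n")
    comment = f"t={time:.6g}"
    if box is not None:
        comment += " box=" + ",".join(f"{v:.6f}" for v in box)
    fh.write(comment + "\n")
    coords_A = np.asarray(coords_nm) / ANGSTROM_TO_NM
    for s, c in zip(symbols, coords_A):
        fh.write(f"{s} {c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")


def write_structure(path, topology: MolecularTopology, frame: Frame,
                    format: Optional[str] = None) -> None:
    """Write a single frame in PDB, GRO or XYZ format."""
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    names = [a.name for a in topology.atoms]
    elements = [a.element for a in topology.atoms]
    resids = [a.molecule_id for a in topology.atoms]
    resnames = [topology.molecule_name[:3].upper() or "MOL"] * len(names)
    if fmt == "pdb":
        write_pdb(path, frame.coordinates, names, resnames, resids, elements)
    elif fmt == "gro":
        with open(path, "w") as fh:
            _write_gro_frame(fh, names, resnames, resids, frame.coordinates,
                             frame.box, frame.time)
    elif fmt == "xyz":
        with open(path, "w") as fh:
            _write_xyz_frame(fh, elements, frame.coordinates, frame.box, frame.time)
    else:
        raise ConfigError(f"unsupported structure format {fmt!r}")


def write_trajectory(path, trajectory, symbols: Sequence[str],
                     format: str = "xyz") -> None:
    """Write a multi-frame trajectory (XYZ or multi-frame GRO).

    ``symbols`` are per-site labels (elements for atomistic data, bead names
    for CG data); ``trajectory`` may be a :class:`Trajectory` or any iterable
    of objects exposing ``coordinates``/``box``/``time`` (CG frames expose
    ``bead_coordinates`` and are accepted too).
    """
    fmt = format.lower()
    frames = list(trajectory)
    with open(path, "w") as fh:
        for fr in frames:
            coords = fr.coordinates if hasattr(fr, "coordinates") else fr.bead_coordinates
            if fmt == "xyz":
                _write_xyz_frame(fh, symbols, coords, fr.box, fr.time)
            elif fmt == "gro":
                n = coords.shape[0]
                _write_gro_frame(fh, list(symbols), ["MOL"] * n, [0] * n,
                                 coords, fr.box, fr.time)
            else:
                raise ConfigError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# mapping-scheme configuration
# ---------------------------------------------------------------------------

_MAPPING_KEYS = {"molecule", "atoms", "beads", "bonds", "angles"}
_BEAD_KEYS = {"name", "type", "atoms", "weighting"}


def load_mapping_config(path):
    """Load a declarative mapping scheme (YAML; schema in docs/formats.md).

    Returns ``(scheme, cg_topology)`` where ``scheme`` is the ordered list of
    :class:`BeadDefinition`.  The only silent default is
    ``weighting: mass``; every other field either parses or raises
    :class:`ConfigError` naming the offending bead/atom/term.
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"invalid YAML: {exc}", path=path)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: mapping config must be a mapping document")
    unknown = set(doc) - _MAPPING_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("atoms", "beads"):
        if key not in doc:
            raise ConfigError(f"{path}: missing required key {key!r}")
    atom_names = list(doc["atoms"])
    if len(set(atom_names)) != len(atom_names):
        raise ConfigError(f"{path}: duplicate atom names in 'atoms'")
    atom_index = {name: i for i, name in enumerate(atom_names)}

    beads: list[BeadDefinition] = []
    seen = set()
    for entry in doc["beads"]:
        if not isinstance(entry, dict):
            raise ConfigError(f"{path}: each bead must be a mapping")
        unknown = set(entry) - _BEAD_KEYS
        if unknown:
            raise ConfigError(f"{path}: bead has unknown keys {sorted(unknown)}")
        try:
            bname = entry["name"]
            batoms = entry["atoms"]
        except KeyError as exc:
            raise ConfigError(f"{path}: bead missing required key {exc}")
        if bname in seen:
            raise ConfigError(f"{path}: duplicate bead name {bname!r}")
        seen.add(bname)
        members = []
        for aname in batoms:
            if aname not in atom_index:
                raise ConfigError(
                    f"{path}: bead {bname!r} references unknown atom {aname!r}"
                )
            members.append(atom_index[aname])
        weighting = entry.get("weighting", "mass")
        if weighting not in ("mass", "geometric"):
            raise ConfigError(
                f"{path}: bead {bname!r} has invalid weighting {weighting!r}"
            )
        beads.append(
            BeadDefinition(
                bead_name=str(bname),
                bead_type=str(entry.get("type", bname)),
                member_atoms=tuple(members),
                weighting=weighting,
            )
        )

    bead_index = {b.bead_name: i for i, b in enumerate(beads)}

    def _resolve(term, arity, label):
        if len(term) != arity:
            raise ConfigError(f"{path}: {label} term {term} must name {arity} beads")
        out = []
        for bname in term:
            if bname not in bead_index:
                raise ConfigError(
                    f"{path}: {label} term {term} uses undefined bead {bname!r}"
                )
            out.append(bead_index[bname])
        return tuple(out)

    bond_terms = tuple(_resolve(t, 2, "bond") for t in doc.get("bonds", []) or [])
    angle_terms = tuple(_resolve(t, 3, "angle") for t in doc.get("angles", []) or [])
    topo = CGTopology(beads=list(beads), bond_terms=bond_terms, angle_terms=angle_terms)
    return beads, topo


# ---------------------------------------------------------------------------
# force-field export / import
# ---------------------------------------------------------------------------


def export_parameters(force_field: ForceField, topology: CGTopology,
                      format: str = "itp") -> str:
    """Serialize fitted parameters.

    ``itp`` emits GROMACS-style bonded sections: ``[ bonds ]`` lines
    ``i j funct b0 kb`` with funct 1 (harmonic, b0 in nm, kb in
    kJ mol^-1 nm^-2) and ``[ angles ]`` lines ``i j k funct th0 cth`` with
    funct 2 (th0 in degrees, cth in kJ mol^-1 rad^-2); bead indices are
    1-based.  ``structured`` emits the lossless JSON schema documented in
    docs/formats.md.
    """
    force_field.validate_complete(topology)
    if format == "itp":
        lines = ["; bonded parameters exported by cgstack"]
        if topology.bond_terms:
            lines.append("[ bonds ]")
            lines.append(";  i   j  funct   b0(nm)   kb(kJ/mol/nm2)")
            for term in topology.bond_terms:
                p = force_field.bond(term)
                lines.append(
                    f"{term[0] + 1} {term[1] + 1} 1 "
                    f"{p.equilibrium:.3f} {p.force_constant:.1f}"
                )
        if topology.angle_terms:
            lines.append("[ angles ]")
            lines.append(";  i   j   k  funct  th0(deg)  cth(kJ/mol/rad2)")
            for term in topology.angle_terms:
                p = force_field.angle(term)
                lines.append(
                    f"{term[0] + 1} {term[1] + 1} {term[2] + 1} 2 "
                    f"{p.equilibrium:.2f} {p.force_constant:.2f}"
                )
        return "\n".join(lines) + "\n"
    if format == "structured":
        doc = {
            "format": "cgstack-forcefield",
            "version": 1,
            "cutoff_nm": force_field.cutoff,
            "bonds": [
                {
                    "beads": list(term),
                    "equilibrium_nm": p.equilibrium,
                    "force_constant_kj_mol_nm2": p.force_constant,
                }
                for term, p in sorted(force_field.bond_params.items())
            ],
            "angles": [
                {
                    "beads": list(term),
                    "equilibrium_deg": p.equilibrium,
                    "force_constant_kj_mol_rad2": p.force_constant,
                }
                for term, p in sorted(force_field.angle_params.items())
            ],
            "pairs": [
                {"types": list(k), "epsilon_kj_mol": v[0], "sigma_nm": v[1]}
                for k, v in sorted(force_field.pair_params.items())
            ],
        }
        return json.dumps(doc, indent=2) + "\n"
    raise ConfigError(f"unsupported export format {format!r}")


def import_parameters(text: str) -> ForceField:
    """Parse the structured JSON serialization back into a ForceField."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}")
    if doc.get("format") != "cgstack-forcefield":
        raise ParseError("not a cgstack-forcefield document")
    bond_params = {
        tuple(e["beads"]): HarmonicParams(
            e["equilibrium_nm"], e["force_constant_kj_mol_nm2"]
        )
        for e in doc.get("bonds", [])
    }
    angle_params = {
        tuple(e["beads"]): HarmonicParams(
            e["equilibrium_deg"], e["force_constant_kj_mol_rad2"]
        )
        for e in doc.get("angles", [])
    }
    pair_params = {
        tuple(e["types"]): (e["epsilon_kj_mol"], e["sigma_nm"])
        for e in doc.get("pairs", [])
    }
    return ForceField(
        bond_params=bond_params,
        angle_params=angle_params,
        pair_params=pair_params,
        cutoff=doc.get("cutoff_nm", DEFAULT_CUTOFF),
    )
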