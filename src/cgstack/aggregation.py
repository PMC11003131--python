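"""Structural analyses of multi-molecule scenes.

Planar "stacker" molecules (a geometric stand-in for protoporphyrin-IX-like
tetrapyrroles) aggregate face-to-face into rod-like stacks.  This module
detects clusters (single linkage under a contact cutoff), quantifies their
shape with the gyration tensor (asphericity, relative shape anisotropy
kappa^2), measures stacking geometry (plane normals, inter-plane
separations, in-plane rotation angles between neighbours) and classifies
where an additive sits relative to a stack: intercalated between planes,
adsorbed at the surface, in a co-existing cluster of its own, or free.

Conventions (all surfaced as parameters and recorded in output tables):
contact cutoff 0.6 nm, plane-alignment tolerance 30 deg, neighbour
separation window [0.3, 0.7] nm, lateral radius 1.5x the stacker core
radius of gyration.  Rotation angles are measured counter-clockwise about
the co-oriented stack normal and mapped to [0, 360), so 90 and 270 are
distinct bins.  Minimum-image distances are used whenever a scene has a
box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from cgstack.core_io import MolecularTopology
from cgstack.errors import DegenerateInputError, CGStackError

STACKER = "stacker"

DEFAULT_CONTACT_CUTOFF = 0.6  # nm
DEFAULT_ALIGNMENT_TOL = 30.0  # degrees
DEFAULT_SEPARATION_WINDOW = (0.3, 0.7)  # nm
#: an additive counts as "between consecutive planes" only if the flanking
#: gap is below this multiple of the median inter-plane spacing
MAX_GAP_FACTOR = 2.8


@dataclass
class SceneMolecule:
    """One molecule instance: topology reference, coordinates, species label.

    ``species`` is ``"stacker"`` for the planar aggregating molecule or
    ``"additive:<name>"`` for anything else.
    """

    topology: MolecularTopology
    coordinates: np.ndarray
    species: str = STACKER

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate block {self.coordinates.shape} does not match "
                f"topology with {self.topology.n_atoms} atoms"
            )
        if not self.species:
            raise ValueError("species label must be non-empty")

    @property
    def is_stacker(self) -> bool:
        return self.species == STACKER

    @property
    def centroid(self) -> np.ndarray:
        return self.coordinates.mean(axis=0)


@dataclass
class Scene:
    """A snapshot of many molecules, optionally in an orthorhombic box."""

    molecules: list[SceneMolecule]
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def stacker_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.molecules) if m.is_stacker]

    @property
    def additive_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.molecules) if not m.is_stacker]


@dataclass
class ClusterResult:
    """Single-linkage partition of molecules into contact clusters."""

    assignment: np.ndarray  # cluster id per molecule, contiguous from 0
    sizes: np.ndarray  # molecule count per cluster
    contact_cutoff: float

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.assignment.size and self.sizes.sum() != self.assignment.size:
            raise ValueError("cluster sizes must sum to molecule count")

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)


@dataclass
class ShapeMetrics:
    """Gyration-tensor descriptors of a point set (nm^2)."""

    eigenvalues: np.ndarray  # lambda1 >= lambda2 >= lambda3
    asphericity: float
    kappa2: float  # relative shape anisotropy in [0, 1]


@dataclass
class StackGeometry:
    """Per-stacker plane normals and neighbour-pair stacking descriptors.

    ``stacker_indices[k]`` maps row k of ``normals``/``centroids`` back to
    the scene molecule index.  ``neighbor_pairs`` holds (lower, upper) row
    indices ordered along the stack axis, with ``separations`` (nm, > 0)
    and ``rotation_angles`` (degrees in [0, 360)) aligned to it.
    """

    stacker_indices: list[int]
    normals: np.ndarray
    centroids: np.ndarray
    mean_axis: np.ndarray
    neighbor_pairs: list[tuple[int, int]]
    separations: np.ndarray
    rotation_angles: np.ndarray

    def __post_init__(self):
        if len(self.normals):
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("normals must be unit vectors")
        if np.any(self.separations <= 0):
            raise ValueError("separations must be > 0")
        if self.rotation_angles.size and (
            np.any(self.rotation_angles < 0) or np.any(self.rotation_angles >= 360)
        ):
            raise ValueError("rotation angles must lie in [0, 360)")


# ---------------------------------------------------------------------------
# distances & clustering
# ---------------------------------------------------------------------------


def _min_image_diff(a: np.ndarray, b: np.ndarray, box) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        d -= np.round(d / box) * box
    return d


def _molecule_min_distance(mol_a: SceneMolecule, mol_b: SceneMolecule, box) -> float:
    if box is None:
        return float(cdist(mol_a.coordinates, mol_b.coordinates).min())
    d = _min_image_diff(mol_a.coordinates, mol_b.coordinates, box)
    return float(np.sqrt((d ** 2).sum(axis=-1)).min())


def _connected_components(n: int, edges) -> np.ndarray:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = [find(i) for i in range(n)]
    ids: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in ids:
            ids[r] = len(ids)
        out[i] = ids[r]
    return out


def find_clusters(scene: Scene, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                  molecule_indices: Optional[Sequence[int]] = None) -> ClusterResult:
    """Single-linkage clusters: molecules linked iff their minimum
    inter-molecular site distance (minimum image under PBC) < cutoff.

    ``molecule_indices`` restricts clustering to a subset (e.g. stackers
    only); the assignment array then covers just that subset, in order.
    """
    if not contact_cutoff > 0:
        raise ValueError("contact_cutoff must be > 0")
    idx = list(molecule_indices) if molecule_indices is not None \
        else list(range(len(scene.molecules)))
    mols = [scene.molecules[i] for i in idx]
    n = len(mols)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if _molecule_min_distance(mols[i], mols[j], scene.box) < contact_cutoff:
                edges.append((i, j))
    assignment = _connected_components(n, edges)
    sizes = np.bincount(assignment) if n else np.zeros(0, dtype=int)
    return ClusterResult(assignment=assignment, sizes=sizes,
                         contact_cutoff=contact_cutoff)


def cluster_shape(site_coordinates: np.ndarray) -> ShapeMetrics:
    """Gyration-tensor shape metrics of a set of sites.

    asphericity = l1 - (l2+l3)/2;
    kappa^2 = 1 - 3(l1 l2 + l2 l3 + l3 l1)/(l1+l2+l3)^2, which is 1 for a
    line and 0 for spherical symmetry.  A single site gives all zeros by
    convention.
    """
    coords = np.asarray(site_coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("site coordinates must have shape (n, 3)")
    if coords.shape[0] < 2:
        return ShapeMetrics(np.zeros(3), 0.0, 0.0)
    centered = coords - coords.mean(axis=0)
    gyr = centered.T @ centered / coords.shape[0]
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    asph = lam[0] - 0.5 * (lam[1] + lam[2])
    if total <= 0:
        kappa2 = 0.0
    else:
        kappa2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / total ** 2
        kappa2 = min(max(kappa2, 0.0), 1.0)
    return ShapeMetrics(lam, float(asph), float(kappa2))


# ---------------------------------------------------------------------------
# stacking geometry
# ---------------------------------------------------------------------------


def _plane_normal(core_coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane (smallest covariance eigenvector)."""
    centered = core_coords - core_coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[1] < 1e-12 * max(w[2], 1e-30) or w[1] < 1e-18:
        raise DegenerateInputError("degenerate plane: core atoms are collinear")
    return v[:, 0] / np.linalg.norm(v[:, 0])


def _reference_axis_vector(mol: SceneMolecule) -> np.ndarray:
    if mol.topology.reference_axis is None:
        raise DegenerateInputError(
            f"stacker {mol.topology.molecule_name!r} has no reference_axis"
        )
    a, b = mol.topology.reference_axis
    return mol.coordinates[b] - mol.coordinates[a]


def stack_analysis(scene: Scene,
                   alignment_tolerance_deg: float = DEFAULT_ALIGNMENT_TOL,
                   separation_window: tuple[float, float] = DEFAULT_SEPARATION_WINDOW,
                   ) -> StackGeometry:
    """Plane normals, stacked-neighbour pairs and inter-plane rotations.

    Two stackers are neighbours when their plane normals agree within the
    alignment tolerance and their centroid separation projected on the
    mean normal falls inside the separation window.  Normals are
    co-oriented by propagating the first molecule's sign, and the rotation
    angle of each pair is the signed (counter-clockwise) angle between the
    two in-plane reference-axis vectors about the shared normal, mapped to
    [0, 360).
    """
    stacker_idx = scene.stacker_indices
    mols = [scene.molecules[i] for i in stacker_idx]
    n = len(mols)
    normals = np.zeros((n, 3))
    centroids = np.zeros((n, 3))
    for k, mol in enumerate(mols):
        core = mol.topology.core_atoms or tuple(range(mol.topology.n_atoms))
        if len(core) < 3:
            raise DegenerateInputError(
                f"stacker {k} needs >= 3 core atoms to define a plane"
            )
        normals[k] = _plane_normal(mol.coordinates[list(core)])
        centroids[k] = mol.coordinates[list(core)].mean(axis=0)

    # co-orient normals with the first molecule
    for k in range(1, n):
        if normals[k] @ normals[0] < 0:
            normals[k] = -normals[k]
    if n:
        mean_axis = normals.sum(axis=0)
        norm = np.linalg.norm(mean_axis)
        mean_axis = mean_axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    else:
        mean_axis = np.array([0.0, 0.0, 1.0])

    cos_tol = math.cos(math.radians(alignment_tolerance_deg))
    lo, hi = separation_window
    pairs: list[tuple[int, int]] = []
    seps: list[float] = []
    angles: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(float(normals[i] @ normals[j])) < cos_tol:
                continue
            d = centroids[j] - centroids[i]
            if scene.box is not None:
                d = d - np.round(d / scene.box) * scene.box
            sep = float(d @ mean_axis)
            if not lo <= abs(sep) <= hi:
                continue
            lowk, upk = (i, j) if sep > 0 else (j, i)
            n_shared = normals[i] + normals[j]
            n_shared = n_shared / np.linalg.norm(n_shared)
            a_vec = _reference_axis_vector(mols[lowk])
            b_vec = _reference_axis_vector(mols[upk])
            a_p = a_vec - (a_vec @ n_shared) * n_shared
            b_p = b_vec - (b_vec @ n_shared) * n_shared
            na, nb_ = np.linalg.norm(a_p), np.linalg.norm(b_p)
            if na < 1e-12 or nb_ < 1e-12:
                raise DegenerateInputError(
                    "reference axis parallel to the stack normal"
                )
            ang = math.degrees(
                math.atan2(float(n_shared @ np.cross(a_p, b_p)),
                           float(a_p @ b_p))
            ) % 360.0
            pairs.append((lowk, upk))
            seps.append(abs(sep))
            angles.append(ang)

    return StackGeometry(
        stacker_indices=stacker_idx,
        normals=normals,
        centroids=centroids,
        mean_axis=mean_axis,
        neighbor_pairs=pairs,
        separations=np.asarray(seps),
        rotation_angles=np.asarray(angles),
    )


ROTATION_BINS = (0, 90, 180, 270)
PERMITTED_BINS = frozenset({90, 270})


def classify_rotation(angle_deg: float, bin_tolerance_deg: float = 10.0):
    """Assign a rotation angle to the nearest of {0, 90, 180, 270} (cyclic).

    Returns ``(bin, permitted)`` where ``bin`` is an int or ``"other"`` if
    no bin lies within the tolerance.  Only quarter rotations of 90 and 270
    are permitted in the crystalline stacking pattern; 0 and 180 are not.
    """
    if not 0 <= angle_deg < 360:
        raise ValueError("angle must lie in [0, 360)")
    if bin_tolerance_deg >= 45:
        raise ValueError("bin tolerance >= 45 deg makes rotation bins overlap")
    best_bin = None
    best_d = 1e30
    for b in ROTATION_BINS:
        d = abs(angle_deg - b)
        d = min(d, 360 - d)
        if d < best_d:
            best_d = d
            best_bin = b
    if best_d <= bin_tolerance_deg:
        return best_bin, best_bin in PERMITTED_BINS
    return "other", False


# ---------------------------------------------------------------------------
# additive placement
# ---------------------------------------------------------------------------


def _core_radius_of_gyration(mol: SceneMolecule) -> float:
    core = mol.topology.core_atoms or tuple(range(mol.topology.n_atoms))
    coords = mol.coordinates[list(core)]
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def classify_placement(scene: Scene, additive_index: int,
                       stack_geometry: StackGeometry,
                       cluster_result: ClusterResult,
                       contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                       lateral_radius: Optional[float] = None,
                       attach_cutoff: Optional[float] = None) -> str:
    """Classify one additive as intercalated / surface / co_cluster / free.

    Checked in that order, so the labels are mutually exclusive and
    exhaustive:

    * **intercalated** — any additive site projects strictly between two
      consecutive stacker planes along the stack axis (flanking gap at most
      ``MAX_GAP_FACTOR`` times the median inter-plane spacing) and lies
      within ``lateral_radius`` of the stack axis (default 1.5x the stacker
      core radius of gyration);
    * **surface** — shares a single-linkage cluster with a stacker and has
      a site within ``contact_cutoff`` of a stacker site;
    * **co_cluster** — belongs to a cluster of >= 2 additives whose minimum
      distance to a stacker site is below ``attach_cutoff`` (default
      2x ``contact_cutoff``; an additive cluster *touching* stackers at
      contact range would be labelled surface by the previous rule);
    * **free** — otherwise.

    ``cluster_result`` must be the single-linkage clustering of the whole
    scene at ``contact_cutoff``.
    """
    stacker_idx = scene.stacker_indices
    if not stacker_idx:
        raise CGStackError("scene contains no stacker molecules")
    additive = scene.molecules[additive_index]
    if additive.is_stacker:
        raise ValueError(f"molecule {additive_index} is a stacker, not an additive")
    if attach_cutoff is None:
        attach_cutoff = 2.0 * contact_cutoff
    if lateral_radius is None:
        lateral_radius = 1.5 * _core_radius_of_gyration(
            scene.molecules[stacker_idx[0]]
        )

    # --- intercalated ---
    axis = stack_geometry.mean_axis
    centroids = stack_geometry.centroids
    if len(centroids) >= 2:
        origin = centroids.mean(axis=0)
        t_planes = np.sort((centroids - origin) @ axis)
        gaps = np.diff(t_planes)
        pos_gaps = gaps[gaps > 1e-9]
        median_gap = float(np.median(pos_gaps)) if pos_gaps.size else 0.0
        max_gap = MAX_GAP_FACTOR * median_gap if median_gap > 0 else 0.0
        rel = additive.coordinates - origin
        t_sites = rel @ axis
        lat = np.linalg.norm(rel - np.outer(t_sites, axis), axis=1)
        for t_s, l_s in zip(t_sites, lat):
            if l_s > lateral_radius:
                continue
            k = np.searchsorted(t_planes, t_s)
            if k == 0 or k == t_planes.size:
                continue  # beyond the stack ends
            gap = t_planes[k] - t_planes[k - 1]
            if gap <= 1e-9 or (max_gap and gap > max_gap):
                continue
            if t_planes[k - 1] < t_s < t_planes[k]:
                return "intercalated"

    # --- surface ---
    my_cluster = cluster_result.assignment[additive_index]
    shares_cluster = any(
        cluster_result.assignment[i] == my_cluster for i in stacker_idx
    )
    min_dist_to_stacker = min(
        _molecule_min_distance(additive, scene.molecules[i], scene.box)
        for i in stacker_idx
    )
    if shares_cluster and min_dist_to_stacker < contact_cutoff:
        return "surface"

    # --- co_cluster ---
    add_idx = scene.additive_indices
    add_clusters = find_clusters(scene, contact_cutoff, molecule_indices=add_idx)
    pos = add_idx.index(additive_index)
    my_add_cluster = add_clusters.assignment[pos]
    members = [add_idx[k] for k in range(len(add_idx))
               if add_clusters.assignment[k] == my_add_cluster]
    if len(members) >= 2:
        cluster_dist = min(
            _molecule_min_distance(scene.molecules[m], scene.molecules[i], scene.box)
            for m in members
            for i in stacker_idx
        )
        if cluster_dist < attach_cutoff:
            return "co_cluster"

    return "free"


def classify_placements(scene: Scene,
                        contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                        alignment_tolerance_deg: float = DEFAULT_ALIGNMENT_TOL,
                        separation_window=DEFAULT_SEPARATION_WINDOW,
                        lateral_radius: Optional[float] = None,
                        attach_cutoff: Optional[float] = None) -> dict[int, str]:
    """Placement labels for every additive in a scene (computes the stack
    geometry and whole-scene clustering internally)."""
    geometry = stack_analysis(scene, alignment_tolerance_deg, separation_window)
    clusters = find_clusters(scene, contact_cutoff)
    return {
        i: classify_placement(scene, i, geometry, clusters, contact_cutoff,
                              lateral_radius, attach_cutoff)
        for i in scene.additive_indices
    }


# ---------------------------------------------------------------------------
# scene-level summaries
# ---------------------------------------------------------------------------


def stacker_cluster_sizes(scene: Scene,
                          contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """Cluster sizes over stacker molecules only (additives excluded).

    This is the disruption metric: an intercalated additive bridges two
    stack segments under single linkage, so the stacker-only clustering is
    what reveals stacks split at intercalation points.
    """
    idx = scene.stacker_indices
    res = find_clusters(scene, contact_cutoff, molecule_indices=idx)
    return res.sizes


def stacker_shape(scene: Scene) -> ShapeMetrics:
    """Gyration-tensor shape of all stacker sites in the scene."""
    idx = scene.stacker_indices
    if not idx:
        raise CGStackError("scene contains no stacker molecules")
    coords = np.concatenate([scene.molecules[i].coordinates for i in idx])
    return cluster_shape(coords)


# ---------------------------------------------------------------------------
# scene I/O (PDB; resname STK marks stackers)
# ---------------------------------------------------------------------------


def write_scene(path, scene: Scene) -> None:
    """Write a scene as a PDB file; residues are molecules, resname ``STK``
    marks stackers and the first three letters of the additive name mark
    additives."""
    from cgstack.core_io import write_pdb

    coords, names, resnames, resids, elements = [], [], [], [], []
    for mol_id, mol in enumerate(scene.molecules):
        if mol.is_stacker:
            resname = "STK"
        else:
            tag = mol.species.split(":", 1)[-1] or "ADT"
            resname = tag[:3].upper()
        for a, atom in enumerate(mol.topology.atoms):
            coords.append(mol.coordinates[a])
            names.append(atom.name)
            resnames.append(resname)
            resids.append(mol_id)
            elements.append(atom.element)
    write_pdb(path, np.asarray(coords), names, resnames, resids, elements)


def read_scene(path) -> Scene:
    """Read a scene back from PDB.  Molecules are residues; resname ``STK``
    is a stacker.  Stacker topologies get ``core_atoms = all`` and the
    conventional ``reference_axis = (0, 1)`` (first two atoms)."""
    from cgstack.core_io import AtomRecord, element_mass, read_pdb_records

    records = read_pdb_records(path)
    groups: dict[int, list] = {}
    order: list[int] = []
    for r in records:
        if r.resid not in groups:
            groups[r.resid] = []
            order.append(r.resid)
        groups[r.resid].append(r)
    molecules = []
    for mol_id, resid in enumerate(order):
        recs = groups[resid]
        atoms = [
            AtomRecord(name=r.name, element=r.element,
                       mass=element_mass(r.element), molecule_id=mol_id)
            for r in recs
        ]
        coords = np.array([r.xyz for r in recs]) * 0.1  # Angstrom -> nm
        is_stacker = recs[0].resname.upper() == "STK"
        if is_stacker and len(atoms) >= 3:
            topo = MolecularTopology(
                molecule_name="STK", atoms=atoms,
                core_atoms=tuple(range(len(atoms))), reference_axis=(0, 1),
            )
            species = STACKER
        else:
            topo = MolecularTopology(
                molecule_name=recs[0].resname or "ADT", atoms=atoms
            )
            species = STACKER if is_stacker else f"additive:{recs[0].resname.lower()}"
        molecules.append(SceneMolecule(topo, coords, species))
    return Scene(molecules)
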