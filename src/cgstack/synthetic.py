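"""Synthetic inputs with known ground truth.

Two families of generators make the pipeline testable end to end without
any external data:

* :func:`gen_bonded_trajectory` builds single-molecule CG trajectories
  whose bond-length and bond-angle marginals follow prescribed Gaussians —
  exactly the statistical structure harmonic Boltzmann inversion assumes —
  by sequential placement along the bond tree (bond lengths and angles
  drawn from their Gaussians, torsions uniform).
* :func:`gen_stack_scene` / :func:`gen_aggregate_scene` build multi-molecule
  scenes of stacked planar molecules with controlled inter-plane rotations,
  rod or sphere cluster geometry, and additive placement (intercalated /
  surface / free / co-clustered), so every aggregation analysis can be
  checked against the construction parameters.

The stacker template is a square planar 4-site molecule (site radius
0.3 nm) with reference axis (0, 1) — a deliberate geometric abstraction of
a porphine core.  Scene defaults (0.4 nm inter-plane spacing, quarter-turn
rotation steps) mirror the crystalline stacking regime the analyses are
meant to resolve, at reduced molecule counts; the 100:14 stacker:additive
composition ratio of the reference systems is exposed via
:func:`reduced_composition`.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from cgstack.aggregation import Scene, SceneMolecule, STACKER
from cgstack.core_io import AtomRecord, CGTopology, MolecularTopology
from cgstack.errors import ConfigError
from cgstack.mapping import CGFrame, CGTrajectory

#: stacker:additive molecule-count ratio of the reference compositions
COMPOSITION_RATIO = (100, 14)


def reduced_composition(n_stackers: int) -> tuple[int, int]:
    """Reduced-scale composition preserving the 100:14 stacker:additive ratio."""
    s, a = COMPOSITION_RATIO
    return n_stackers, max(1, round(n_stackers * a / s))


# ---------------------------------------------------------------------------
# bonded trajectories
# ---------------------------------------------------------------------------


def _bond_tree(topology: CGTopology):
    """Adjacency + BFS parent order; raises on cycles."""
    n = topology.n_beads
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in topology.bond_terms:
        adj[i].append(j)
        adj[j].append(i)
    if len(topology.bond_terms) >= n and n > 0:
        raise ConfigError("chain/tree required: bond graph contains a cycle")
    order = []
    parent = [-1] * n
    visited = [False] * n
    for root in range(n):
        if visited[root]:
            continue
        stack = [root]
        visited[root] = True
        while stack:
            u = stack.pop(0)
            order.append(u)
            for w in adj[u]:
                if visited[w]:
                    if w != parent[u]:
                        raise ConfigError(
                            "chain/tree required: bond graph contains a cycle"
                        )
                    continue
                visited[w] = True
                parent[w] = u
                stack.append(w)
    return order, parent


def _lookup(table: dict, term):
    if term in table:
        return table[term]
    rev = tuple(reversed(term))
    if rev in table:
        return table[rev]
    raise ConfigError(f"no ground-truth parameters for term {term}")


def _unit(v):
    return v / np.linalg.norm(v)


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return _unit(v)


def gen_bonded_trajectory(topology: CGTopology, ground_truth: dict,
                          n_frames: int, seed: int) -> CGTrajectory:
    """Trajectory whose bonded marginals follow stated Gaussians.

    ``ground_truth`` maps each bond term to ``(mean_nm, sigma_nm)`` and
    each angle term to ``(mean_deg, sigma_deg)``.  Frames are built by
    sequential placement along the bond tree: each bond length is drawn
    from its Gaussian, each declared angle from its Gaussian (torsion
    uniform); beads without a declared angle get a uniform direction on
    the sphere.  The bond graph must be acyclic.  Identical seeds give
    bitwise-identical output.
    """
    order, parent = _bond_tree(topology)
    rng = np.random.default_rng(seed)
    n = topology.n_beads

    # angle lookup: for child c with parent p, find an angle term with
    # vertex p joining c to an already-placed neighbour g
    angle_for = {}
    angle_set = {t: t for t in topology.angle_terms}
    placed_before = {}
    seen: set[int] = set()
    for u in order:
        placed_before[u] = set(seen)
        seen.add(u)
    for c in order:
        p = parent[c]
        if p < 0:
            continue
        for t in topology.angle_terms:
            a, b, cc = t
            if b != p:
                continue
            if a == c and cc in placed_before[c]:
                angle_for[c] = (t, cc)
                break
            if cc == c and a in placed_before[c]:
                angle_for[c] = (t, a)
                break

    frames = []
    for k in range(n_frames):
        coords = np.zeros((n, 3))
        for c in order:
            p = parent[c]
            if p < 0:
                # component root; offset components to keep them distinct
                coords[c] = np.array([0.0, 0.0, 0.0]) if c == 0 \
                    else coords[c] + c * 2.0
                continue
            mean, sigma = _lookup(ground_truth, (p, c))
            r = abs(rng.normal(mean, sigma))
            if c in angle_for:
                term, g = angle_for[c]
                amean, asigma = _lookup(ground_truth, term)
                theta = rng.normal(amean, asigma)
                theta = min(max(theta, 1e-3), 180.0 - 1e-3)
                e1 = _unit(coords[g] - coords[p])
                # orthonormal complement of e1
                helper = np.array([1.0, 0.0, 0.0])
                if abs(e1 @ helper) > 0.9:
                    helper = np.array([0.0, 1.0, 0.0])
                e2 = _unit(np.cross(e1, helper))
                e3 = np.cross(e1, e2)
                phi = rng.uniform(0.0, 2.0 * math.pi)
                th = math.radians(theta)
                d = (math.cos(th) * e1
                     + math.sin(th) * (math.cos(phi) * e2 + math.sin(phi) * e3))
            else:
                d = _random_unit(rng)
            coords[c] = coords[p] + r * d
        frames.append(CGFrame(coords.copy(), time=float(k)))
    return CGTrajectory(frames)


# ---------------------------------------------------------------------------
# scene templates
# ---------------------------------------------------------------------------

_STACKER_RADIUS = 0.3  # nm, site distance from the molecular centre


def stacker_template() -> tuple[MolecularTopology, np.ndarray]:
    """Square planar 4-site stacker with reference axis (0, 1)."""
    r = _STACKER_RADIUS
    coords = np.array(
        [[r, 0.0, 0.0], [0.0, r, 0.0], [-r, 0.0, 0.0], [0.0, -r, 0.0]]
    )
    atoms = [AtomRecord(name=f"C{i + 1}", element="C", mass=12.011, molecule_id=0)
             for i in range(4)]
    topo = MolecularTopology(
        molecule_name="STK", atoms=atoms,
        bonds={(0, 1), (1, 2), (2, 3), (3, 0)},
        core_atoms=(0, 1, 2, 3), reference_axis=(0, 1),
    )
    return topo, coords


def additive_template() -> tuple[MolecularTopology, np.ndarray]:
    """Linear 3-site additive (0.25 nm site spacing along x)."""
    coords = np.array([[-0.25, 0.0, 0.0], [0.0, 0.0, 0.0], [0.25, 0.0, 0.0]])
    atoms = [AtomRecord(name=f"N{i + 1}", element="N", mass=14.007, molecule_id=0)
             for i in range(3)]
    topo = MolecularTopology(molecule_name="ADT", atoms=atoms,
                             bonds={(0, 1), (1, 2)})
    return topo, coords


def _rot_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# stack scenes
# ---------------------------------------------------------------------------


def gen_stack_scene(n_molecules: int, spacing: float,
                    rotation_sequence: Sequence[float],
                    jitter_sigma: float = 0.0, seed: int = 0) -> Scene:
    """A single stack of planar molecules along z with controlled rotations.

    Molecule m sits at z = m * spacing and is rotated about the stack axis
    by the cumulative sum of ``rotation_sequence`` (degrees; one entry per
    successive pair).  With ``jitter_sigma`` = 0,
    :func:`~cgstack.aggregation.stack_analysis` recovers the spacing and
    every rotation exactly.
    """
    if not spacing > 0:
        raise ConfigError("spacing must be > 0")
    if len(rotation_sequence) != max(n_molecules - 1, 0):
        raise ConfigError(
            f"rotation_sequence must have {max(n_molecules - 1, 0)} entries "
            f"for {n_molecules} molecules"
        )
    rng = np.random.default_rng(seed)
    topo, base = stacker_template()
    molecules = []
    phi = 0.0
    for m in range(n_molecules):
        if m > 0:
            phi += rotation_sequence[m - 1]
        coords = base @ _rot_z(phi).T
        coords = coords + np.array([0.0, 0.0, m * spacing])
        if jitter_sigma > 0:
            coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)
        molecules.append(SceneMolecule(topo, coords, STACKER))
    return Scene(molecules)


# ---------------------------------------------------------------------------
# aggregate scenes with additives
# ---------------------------------------------------------------------------

PLACEMENT_MODES = ("intercalate", "surface", "none", "co_cluster")


def _rod_stackers(n_stackers, spacing, insertion_gaps, rng, jitter_sigma):
    """Stacker molecules along z; gaps in ``insertion_gaps`` (index g =
    between molecules g and g+1) are widened to 2x spacing and their centre
    z returned for additive placement."""
    topo, base = stacker_template()
    molecules = []
    gap_centers = {}
    phis = []
    z = 0.0
    phi = 0.0
    for m in range(n_stackers):
        if m > 0:
            phi += float(rng.choice([90.0, 270.0]))
        phis.append(phi)
        coords = base @ _rot_z(phi).T + np.array([0.0, 0.0, z])
        if jitter_sigma > 0:
            coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)
        molecules.append(SceneMolecule(topo, coords, STACKER))
        if m in insertion_gaps:
            gap_centers[m] = z + spacing
            z += 2.0 * spacing
        else:
            z += spacing
    return molecules, gap_centers, phis


def _sphere_stackers(n_stackers, rng, jitter_sigma):
    """Stackers on a jittered cubic lattice inside a ball, random
    orientations; 0.45 nm lattice spacing keeps the cluster connected at
    the default 0.6 nm contact cutoff."""
    a = 0.45
    pts = []
    r = 1
    while len(pts) < 8 * n_stackers:
        pts = [
            np.array([i, j, k], dtype=float) * a
            for i in range(-r, r + 1)
            for j in range(-r, r + 1)
            for k in range(-r, r + 1)
        ]
        r += 1
    pts.sort(key=lambda p: float(p @ p))
    topo, base = stacker_template()
    molecules = []
    for m in range(n_stackers):
        rot = _random_rotation(rng)
        coords = base @ rot.T + pts[m]
        if jitter_sigma > 0:
            coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)
        molecules.append(SceneMolecule(topo, coords, STACKER))
    return molecules


def gen_aggregate_scene(n_stackers: int, n_additives: int,
                        placement_mode: str = "none", geometry: str = "rod",
                        seed: int = 0, spacing: float = 0.4,
                        jitter_sigma: float = 0.01,
                        contact_cutoff: float = 0.6,
                        additive_species: str = "additive:alkyl") -> Scene:
    """A stacker cluster (rod or sphere) with additives placed by mode.

    Modes: ``intercalate`` inserts each additive between two consecutive
    stack planes, widening that gap to 2x spacing (so the stacker-only
    clustering splits there while the additive bridges the full-scene
    cluster); ``surface`` adsorbs additives at the cluster boundary within
    contact range of a stacker; ``none`` scatters them beyond 3x the
    contact cutoff; ``co_cluster`` builds a compact additive cluster whose
    gap to the stackers lies between the contact cutoff and twice the
    contact cutoff.  ``classify_placement`` on the output returns the
    requested label for every additive.
    """
    if placement_mode not in PLACEMENT_MODES:
        raise ConfigError(f"unknown placement mode {placement_mode!r}")
    if n_stackers < 1 or n_additives < 0:
        raise ConfigError("counts must be non-negative (>= 1 stacker)")
    if placement_mode == "intercalate" and n_stackers < 2:
        raise ConfigError("intercalation needs at least 2 stackers")
    if placement_mode == "intercalate" and geometry != "rod":
        raise ConfigError("intercalation is only defined for rod geometry")
    if placement_mode == "intercalate" and n_additives > n_stackers - 1:
        raise ConfigError("more intercalants than available gaps")
    if placement_mode == "co_cluster" and 0 < n_additives < 2:
        raise ConfigError("a co-cluster needs at least 2 additives")

    rng = np.random.default_rng(seed)
    add_topo, add_base = additive_template()

    insertion_gaps: set[int] = set()
    if placement_mode == "intercalate" and n_additives > 0:
        insertion_gaps = set(
            rng.choice(n_stackers - 1, size=n_additives, replace=False).tolist()
        )

    if geometry == "rod":
        molecules, gap_centers, _ = _rod_stackers(
            n_stackers, spacing, insertion_gaps, rng, jitter_sigma
        )
    elif geometry == "sphere":
        molecules = _sphere_stackers(n_stackers, rng, jitter_sigma)
        gap_centers = {}
    else:
        raise ConfigError(f"unknown geometry {geometry!r}")

    stacker_coords = np.concatenate([m.coordinates for m in molecules])
    r_max = float(np.linalg.norm(stacker_coords, axis=1).max())

    additives = []
    if placement_mode == "intercalate":
        for g in sorted(gap_centers):
            zc = gap_centers[g]
            phi = rng.uniform(0.0, 360.0)
            coords = add_base @ _rot_z(phi).T + np.array([0.0, 0.0, zc])
            coords = coords + rng.normal(0.0, 0.005, coords.shape)
            additives.append(SceneMolecule(add_topo, coords, additive_species))
    elif placement_mode == "surface":
        host = rng.choice(n_stackers, size=n_additives,
                          replace=n_additives > n_stackers)
        for a in range(n_additives):
            mol = molecules[int(host[a])]
            # adsorb along the radial direction of one of the host's sites
            site = mol.coordinates[int(rng.integers(mol.coordinates.shape[0]))]
            center = mol.coordinates.mean(axis=0)
            radial = site - center
            radial = radial / np.linalg.norm(radial)
            pos = site + 0.4 * radial
            # lay the additive perpendicular to the radial direction
            helper = np.array([0.0, 0.0, 1.0])
            if abs(radial @ helper) > 0.9:
                helper = np.array([1.0, 0.0, 0.0])
            tangent = np.cross(radial, helper)
            tangent = tangent / np.linalg.norm(tangent)
            coords = pos + np.outer(np.array([-0.25, 0.0, 0.25]), tangent)
            coords = coords + rng.normal(0.0, 0.005, coords.shape)
            additives.append(SceneMolecule(add_topo, coords, additive_species))
    elif placement_mode == "none":
        for a in range(n_additives):
            d = _random_unit(rng)
            pos = d * (r_max + 3.0 * contact_cutoff + 0.5 + 0.8 * a)
            coords = add_base + pos
            additives.append(SceneMolecule(add_topo, coords, additive_species))
    elif placement_mode == "co_cluster" and n_additives:
        # compact additive stack offset laterally from the cluster; the gap
        # (0.9 nm) sits between contact_cutoff and the 2x attach window
        gap = 1.5 * contact_cutoff
        x_off = _STACKER_RADIUS + gap + 0.25
        z_mid = float(np.median(stacker_coords[:, 2]))
        for a in range(n_additives):
            pos = np.array([x_off, 0.0, z_mid + 0.4 * (a - n_additives / 2)])
            coords = add_base + pos
            coords = coords + rng.normal(0.0, 0.005, coords.shape)
            additives.append(SceneMolecule(add_topo, coords, additive_species))

    return Scene(molecules + additives)
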