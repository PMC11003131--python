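"""Minimal CG dynamics engine: harmonic bonds/angles, truncated LJ pairs,
velocity-Verlet (NVE) and BAOAB Langevin integration.

The engine exists to resimulate a fitted CG model long enough to sample its
bonded marginals, closing the distribution-matching refinement loop.  It is
deliberately small: no electrostatics, constraints or pressure coupling.
Forces and the integrator inner loop are numba-compiled; the public
:func:`compute_forces` wraps the same kernel the integrator uses, so the
finite-difference force test exercises the exact code path of the dynamics.

Units: nm, ps, amu, kJ/mol (1 amu nm^2 ps^-2 = 1 kJ/mol, so no conversion
constants appear).  With friction = 0 the BAOAB scheme reduces exactly to
velocity Verlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from cgstack.constants import DEFAULT_TEMPERATURE, KB
from cgstack.core_io import CGTopology, ForceField
from cgstack.errors import EngineError, MissingParameterError
from cgstack.mapping import CGFrame, CGTrajectory


@dataclass
class EngineConfig:
    """Integration settings.

    friction is the Langevin collision rate in ps^-1; 0 gives NVE.
    neighbor_update_interval controls how often the LJ pair list (plain
    O(N^2) loop with a 0.3 nm skin) is refreshed.
    """

    timestep: float = 0.001  # ps
    n_steps: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0  # ps^-1
    seed: int = 0
    save_interval: int = 1
    box: Optional[Sequence[float]] = None
    neighbor_update_interval: int = 20

    def __post_init__(self):
        if not self.timestep > 0:
            raise ValueError("timestep must be > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive edge lengths")


@dataclass
class DynamicsResult:
    """Sampled trajectory plus per-saved-frame energy diagnostics."""

    trajectory: CGTrajectory
    times: np.ndarray  # ps
    potential_energies: np.ndarray  # kJ/mol
    kinetic_energies: np.ndarray  # kJ/mol
    temperatures: np.ndarray  # K (centre-of-mass motion removed)

    @property
    def total_energies(self) -> np.ndarray:
        return self.potential_energies + self.kinetic_energies

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ps": self.times,
                "potential_kj_mol": self.potential_energies,
                "kinetic_kj_mol": self.kinetic_energies,
                "total_kj_mol": self.total_energies,
                "temperature_K": self.temperatures,
            }
        )


# ---------------------------------------------------------------------------
# parameter flattening
# ---------------------------------------------------------------------------


class _System:
    """Flat numeric arrays for the jitted kernels."""

    def __init__(self, force_field: ForceField, topology: CGTopology):
        force_field.validate_complete(topology)
        nb = len(topology.bond_terms)
        self.bond_i = np.array([t[0] for t in topology.bond_terms], dtype=np.int64)
        self.bond_j = np.array([t[1] for t in topology.bond_terms], dtype=np.int64)
        self.bond_r0 = np.empty(nb)
        self.bond_k = np.empty(nb)
        for n, t in enumerate(topology.bond_terms):
            p = force_field.bond(t)
            self.bond_r0[n] = p.equilibrium
            self.bond_k[n] = p.force_constant

        na = len(topology.angle_terms)
        self.ang_a = np.array([t[0] for t in topology.angle_terms], dtype=np.int64)
        self.ang_b = np.array([t[1] for t in topology.angle_terms], dtype=np.int64)
        self.ang_c = np.array([t[2] for t in topology.angle_terms], dtype=np.int64)
        self.ang_t0 = np.empty(na)
        self.ang_k = np.empty(na)
        for n, t in enumerate(topology.angle_terms):
            p = force_field.angle(t)
            self.ang_t0[n] = math.radians(p.equilibrium)
            self.ang_k[n] = p.force_constant

        # LJ candidate pairs: all bead pairs with declared type parameters,
        # excluding first (1-2) and second (1-3) bonded neighbours
        excl = set()
        for i, j in topology.bond_terms:
            excl.add((min(i, j), max(i, j)))
        for a, b, c in topology.angle_terms:
            excl.add((min(a, b), max(a, b)))
            excl.add((min(b, c), max(b, c)))
            excl.add((min(a, c), max(a, c)))
        pi, pj, eps, sig = [], [], [], []
        types = [b.bead_type for b in topology.beads]
        n_beads = topology.n_beads
        for i in range(n_beads):
            for j in range(i + 1, n_beads):
                if (i, j) in excl:
                    continue
                params = force_field.pair(types[i], types[j])
                if params is None:
                    continue
                pi.append(i)
                pj.append(j)
                eps.append(params[0])
                sig.append(params[1])
        self.pair_i = np.array(pi, dtype=np.int64)
        self.pair_j = np.array(pj, dtype=np.int64)
        self.pair_eps = np.array(eps, dtype=float)
        self.pair_sig = np.array(sig, dtype=float)
        self.cutoff = float(force_field.cutoff)


@njit(cache=False)
def _forces_kernel(x, f,
                   bond_i, bond_j, bond_r0, bond_k,
                   ang_a, ang_b, ang_c, ang_t0, ang_k,
                   pair_i, pair_j, pair_eps, pair_sig,
                   cutoff2, box, has_box):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    energy = 0.0

    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        if has_box:
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        energy += 0.5 * bond_k[b] * dr * dr
        if r > 0.0:
            fac = bond_k[b] * dr / r  # pulls j toward i when stretched
            f[j, 0] -= fac * dx
            f[j, 1] -= fac * dy
            f[j, 2] -= fac * dz
            f[i, 0] += fac * dx
            f[i, 1] += fac * dy
            f[i, 2] += fac * dz

    for a in range(ang_a.shape[0]):
        ia = ang_a[a]
        ib = ang_b[a]
        ic = ang_c[a]
        ux = x[ia, 0] - x[ib, 0]
        uy = x[ia, 1] - x[ib, 1]
        uz = x[ia, 2] - x[ib, 2]
        vx = x[ic, 0] - x[ib, 0]
        vy = x[ic, 1] - x[ib, 1]
        vz = x[ic, 2] - x[ib, 2]
        if has_box:
            ux -= box[0] * round(ux / box[0])
            uy -= box[1] * round(uy / box[1])
            uz -= box[2] * round(uz / box[2])
            vx -= box[0] * round(vx / box[0])
            vy -= box[1] * round(vy / box[1])
            vz -= box[2] * round(vz / box[2])
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = math.acos(c)
        s = math.sqrt(1.0 - c * c)
        if s < 1.0e-8:
            s = 1.0e-8
        dtheta = theta - ang_t0[a]
        energy += 0.5 * ang_k[a] * dtheta * dtheta
        coef = -ang_k[a] * dtheta / s
        # dtheta/dxa = (c*u_hat - v_hat) / (nu * s); force = -k dtheta dtheta/dx
        fax = coef * (c * ux / nu - vx / nv) / nu
        fay = coef * (c * uy / nu - vy / nv) / nu
        faz = coef * (c * uz / nu - vz / nv) / nu
        fcx = coef * (c * vx / nv - ux / nu) / nv
        fcy = coef * (c * vy / nv - uy / nu) / nv
        fcz = coef * (c * vz / nv - uz / nu) / nv
        f[ia, 0] += fax
        f[ia, 1] += fay
        f[ia, 2] += faz
        f[ic, 0] += fcx
        f[ic, 1] += fcy
        f[ic, 2] += fcz
        f[ib, 0] -= fax + fcx
        f[ib, 1] -= fay + fcy
        f[ib, 2] -= faz + fcz

    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        if has_box:
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cutoff2 or r2 == 0.0:
            continue
        sr2 = pair_sig[p] * pair_sig[p] / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        energy += 4.0 * pair_eps[p] * (sr12 - sr6)
        fac = 24.0 * pair_eps[p] * (2.0 * sr12 - sr6) / r2
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz

    return energy


@njit(cache=False)
def _temperature_kernel(v, masses):
    n = v.shape[0]
    mtot = 0.0
    px = 0.0
    py = 0.0
    pz = 0.0
    for i in range(n):
        mtot += masses[i]
        px += masses[i] * v[i, 0]
        py += masses[i] * v[i, 1]
        pz += masses[i] * v[i, 2]
    vcx = px / mtot
    vcy = py / mtot
    vcz = pz / mtot
    ke2 = 0.0
    for i in range(n):
        ax = v[i, 0] - vcx
        ay = v[i, 1] - vcy
        az = v[i, 2] - vcz
        ke2 += masses[i] * (ax * ax + ay * ay + az * az)
    ndof = 3 * n - 3
    return ke2 / (ndof * KB)


@njit(cache=False)
def _run_kernel(x0, masses, dt, n_steps, gamma, kT, save_interval, seed,
                nupdate,
                bond_i, bond_j, bond_r0, bond_k,
                ang_a, ang_b, ang_c, ang_t0, ang_k,
                cand_i, cand_j, cand_eps, cand_sig,
                cutoff, box, has_box):
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    v = np.empty((n, 3))
    for i in range(n):
        s = math.sqrt(kT / masses[i])
        for d in range(3):
            v[i, d] = s * np.random.normal()

    n_cand = cand_i.shape[0]
    act_i = np.empty(n_cand, dtype=np.int64)
    act_j = np.empty(n_cand, dtype=np.int64)
    act_eps = np.empty(n_cand)
    act_sig = np.empty(n_cand)
    skin = 0.3
    list_cut2 = (cutoff + skin) * (cutoff + skin)
    cutoff2 = cutoff * cutoff

    n_act = 0
    for p in range(n_cand):
        i = cand_i[p]
        j = cand_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        if has_box:
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
        if dx * dx + dy * dy + dz * dz < list_cut2:
            act_i[n_act] = i
            act_j[n_act] = j
            act_eps[n_act] = cand_eps[p]
            act_sig[n_act] = cand_sig[p]
            n_act += 1

    n_saved = n_steps // save_interval + 1
    xs = np.empty((n_saved, n, 3))
    pe = np.empty(n_saved)
    ke = np.empty(n_saved)
    temps = np.empty(n_saved)

    f = np.zeros((n, 3))
    e = _forces_kernel(x, f, bond_i, bond_j, bond_r0, bond_k,
                       ang_a, ang_b, ang_c, ang_t0, ang_k,
                       act_i[:n_act], act_j[:n_act], act_eps[:n_act],
                       act_sig[:n_act], cutoff2, box, has_box)

    kin = 0.0
    for i in range(n):
        kin += 0.5 * masses[i] * (v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
    xs[0] = x
    pe[0] = e
    ke[0] = kin
    temps[0] = _temperature_kernel(v, masses) if n > 1 else 0.0

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    isave = 1
    half_dt = 0.5 * dt

    for step in range(1, n_steps + 1):
        if (step - 1) % nupdate == 0 and n_cand > 0:
            n_act = 0
            for p in range(n_cand):
                i = cand_i[p]
                j = cand_j[p]
                dx = x[i, 0] - x[j, 0]
                dy = x[i, 1] - x[j, 1]
                dz = x[i, 2] - x[j, 2]
                if has_box:
                    dx -= box[0] * round(dx / box[0])
                    dy -= box[1] * round(dy / box[1])
                    dz -= box[2] * round(dz / box[2])
                if dx * dx + dy * dy + dz * dz < list_cut2:
                    act_i[n_act] = i
                    act_j[n_act] = j
                    act_eps[n_act] = cand_eps[p]
                    act_sig[n_act] = cand_sig[p]
                    n_act += 1

        # BAOAB: B(dt/2) A(dt/2) O A(dt/2) [force] B(dt/2)
        ok = True
        for i in range(n):
            inv_m = half_dt / masses[i]
            for d in range(3):
                v[i, d] += inv_m * f[i, d]
                x[i, d] += half_dt * v[i, d]
        if gamma > 0.0:
            for i in range(n):
                s = math.sqrt(kT / masses[i])
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * s * np.random.normal()
        for i in range(n):
            for d in range(3):
                x[i, d] += half_dt * v[i, d]
                if not math.isfinite(x[i, d]):
                    ok = False
        if not ok:
            return xs, pe, ke, temps, step
        e = _forces_kernel(x, f, bond_i, bond_j, bond_r0, bond_k,
                           ang_a, ang_b, ang_c, ang_t0, ang_k,
                           act_i[:n_act], act_j[:n_act], act_eps[:n_act],
                           act_sig[:n_act], cutoff2, box, has_box)
        if not math.isfinite(e):
            return xs, pe, ke, temps, step
        for i in range(n):
            inv_m = half_dt / masses[i]
            for d in range(3):
                v[i, d] += inv_m * f[i, d]

        if step % save_interval == 0:
            kin = 0.0
            for i in range(n):
                kin += 0.5 * masses[i] * (
                    v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
                )
            xs[isave] = x
            pe[isave] = e
            ke[isave] = kin
            temps[isave] = _temperature_kernel(v, masses) if n > 1 else 0.0
            isave += 1

    return xs, pe, ke, temps, 0


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def compute_forces(cg_frame: CGFrame, force_field: ForceField,
                   topology: CGTopology):
    """Analytic forces (kJ mol^-1 nm^-1 per bead) and potential energy.

    Harmonic bonds/angles plus 12-6 LJ pairs truncated (unshifted) at the
    force-field cutoff; pairs separated by one or two bonds are excluded.
    """
    sys_ = _System(force_field, topology)
    x = np.ascontiguousarray(cg_frame.bead_coordinates, dtype=float)
    if x.shape[0] != topology.n_beads:
        raise EngineError(
            f"frame has {x.shape[0]} beads, topology declares {topology.n_beads}"
        )
    f = np.zeros_like(x)
    box = cg_frame.box if cg_frame.box is not None else np.ones(3)
    has_box = cg_frame.box is not None
    energy = _forces_kernel(
        x, f, sys_.bond_i, sys_.bond_j, sys_.bond_r0, sys_.bond_k,
        sys_.ang_a, sys_.ang_b, sys_.ang_c, sys_.ang_t0, sys_.ang_k,
        sys_.pair_i, sys_.pair_j, sys_.pair_eps, sys_.pair_sig,
        sys_.cutoff ** 2, np.asarray(box, dtype=float), has_box,
    )
    return f, float(energy)


def potential_energy(coords: np.ndarray, force_field: ForceField,
                     topology: CGTopology, box=None) -> float:
    """Potential energy of raw coordinates (used by numerical gradients)."""
    frame = CGFrame(coords, box=None if box is None else np.asarray(box))
    return compute_forces(frame, force_field, topology)[1]


def run_dynamics(initial_frame: CGFrame, force_field: ForceField,
                 topology: CGTopology, config: EngineConfig,
                 masses: Sequence[float]) -> DynamicsResult:
    """Integrate the CG model and return sampled frames plus diagnostics.

    BAOAB-splitting Langevin dynamics; ``config.friction == 0`` reduces
    exactly to velocity Verlet (NVE).  Initial velocities are drawn from
    the Maxwell-Boltzmann distribution at ``config.temperature`` using
    ``config.seed``; an identical seed and config reproduces the trajectory
    bitwise.  Frames (and energy diagnostics) are recorded every
    ``save_interval`` steps, starting with the initial frame.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.shape != (topology.n_beads,):
        raise EngineError("need one mass per bead")
    if not np.all(masses > 0):
        raise EngineError("masses must be positive")
    x0 = np.ascontiguousarray(initial_frame.bead_coordinates, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise EngineError("initial coordinates must be finite")
    sys_ = _System(force_field, topology)

    box_cfg = config.box if config.box is not None else initial_frame.box
    has_box = box_cfg is not None
    box = np.asarray(box_cfg, dtype=float) if has_box else np.ones(3)

    xs, pe, ke, temps, err_step = _run_kernel(
        x0, masses, config.timestep, config.n_steps, config.friction,
        KB * config.temperature, config.save_interval, config.seed,
        config.neighbor_update_interval,
        sys_.bond_i, sys_.bond_j, sys_.bond_r0, sys_.bond_k,
        sys_.ang_a, sys_.ang_b, sys_.ang_c, sys_.ang_t0, sys_.ang_k,
        sys_.pair_i, sys_.pair_j, sys_.pair_eps, sys_.pair_sig,
        sys_.cutoff, box, has_box,
    )
    if err_step:
        raise EngineError(f"non-finite coordinates or forces at step {err_step}")

    t0 = initial_frame.time
    times = t0 + config.timestep * config.save_interval * np.arange(xs.shape[0])
    frames = [
        CGFrame(xs[k], box=box.copy() if has_box else None, time=times[k])
        for k in range(xs.shape[0])
    ]
    return DynamicsResult(
        trajectory=CGTrajectory(frames),
        times=times,
        potential_energies=pe,
        kinetic_energies=ke,
        temperatures=temps,
    )


def kinetic_temperature(velocities: np.ndarray, masses: Sequence[float]) -> float:
    """Instantaneous kinetic temperature, centre-of-mass motion removed.

    T = sum(m v'^2) / (Ndof kB) with v' the COM-frame velocities and
    Ndof = 3N - 3.
    """
    velocities = np.asarray(velocities, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if velocities.shape[0] != masses.shape[0]:
        raise EngineError("velocity count must equal mass count")
    if masses.shape[0] < 2:
        raise EngineError("kinetic temperature needs at least 2 particles")
    return float(_temperature_kernel(np.ascontiguousarray(velocities), masses))
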