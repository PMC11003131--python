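"""Harmonic Boltzmann inversion of bonded distributions.

For a coordinate whose equilibrium marginal is Gaussian, the potential of
mean force is harmonic:

    U(x) = 1/2 k (x - x0)^2,   x0 = <x>,   k = kB T / Var(x).

Bonds are inverted in nm (k in kJ mol^-1 nm^-2); angles are measured in
degrees at the interface but inverted in radians (k in kJ mol^-1 rad^-2),
matching ITP conventions.  The optional Jacobian correction for angles
reweights samples by 1/sin(theta) to remove the sin(theta) volume element
of the angular measure before taking moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from cgstack.constants import DEFAULT_TEMPERATURE, KB
from cgstack.core_io import BondedDistribution, HarmonicParams
from cgstack.errors import DegenerateInputError


@dataclass(frozen=True)
class ThermoState:
    """Temperature context for the inversion; kB is fixed, not configurable."""

    temperature: float = DEFAULT_TEMPERATURE
    kB: float = field(default=KB, init=False)

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")

    @property
    def kT(self) -> float:
        return self.kB * self.temperature


def _check_variance(variance: float, mean: float, term) -> None:
    # relative floor guards against float noise on constant samples
    floor = (1e-9 * max(abs(mean), 1e-9)) ** 2
    if variance <= floor:
        raise DegenerateInputError(
            f"degenerate distribution for term {term}: zero variance"
        )


def fit_bond_harmonic(dist: BondedDistribution, thermo: ThermoState) -> HarmonicParams:
    """Invert a bond-length marginal: r0 = mean, k = kB T / variance."""
    if dist.kind != "bond":
        raise ValueError(f"expected a bond distribution, got kind={dist.kind!r}")
    if np.any(dist.samples < 0):
        raise DegenerateInputError("bond samples must be non-negative")
    _check_variance(dist.variance, dist.mean, dist.term)
    return HarmonicParams(
        equilibrium=dist.mean,
        force_constant=thermo.kT / dist.variance,
    )


def fit_angle_harmonic(dist: BondedDistribution, thermo: ThermoState,
                       jacobian_correct: bool = False) -> HarmonicParams:
    """Invert a bond-angle marginal.

    Returns the equilibrium angle in degrees and the force constant in
    kJ mol^-1 rad^-2 (variance converted to rad^2 before inversion).  With
    ``jacobian_correct``, moments are taken under 1/sin(theta) weights;
    samples touching 0 or 180 degrees then make the weight diverge and
    raise an error.
    """
    if dist.kind != "angle":
        raise ValueError(f"expected an angle distribution, got kind={dist.kind!r}")
    samples = dist.samples
    if np.any(samples <= 0) or np.any(samples >= 180):
        if jacobian_correct:
            raise DegenerateInputError(
                "angle samples at 0 or 180 degrees: 1/sin weight diverges"
            )
    if jacobian_correct:
        theta = np.radians(samples)
        sin_theta = np.sin(theta)
        if np.any(sin_theta <= 0):
            raise DegenerateInputError(
                "angle samples at 0 or 180 degrees: 1/sin weight diverges"
            )
        w = 1.0 / sin_theta
        wsum = w.sum()
        mean = float((w * samples).sum() / wsum)
        n = samples.size
        var = float((w * (samples - mean) ** 2).sum() / wsum) * n / (n - 1)
    else:
        mean = dist.mean
        var = dist.variance
    _check_variance(var, mean, dist.term)
    var_rad2 = var * (math.pi / 180.0) ** 2
    return HarmonicParams(
        equilibrium=mean,
        force_constant=thermo.kT / var_rad2,
    )
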