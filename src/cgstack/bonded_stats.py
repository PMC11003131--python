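"""Bond-length and bond-angle time series, distribution summaries, and a
bounded divergence for comparing two bonded marginals.

All inter-bead displacements honour the minimum-image convention when a
frame carries a box.  Bond samples are nm; angle samples are degrees in
[0, 180] with the middle bead as vertex.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from cgstack.core_io import BondedDistribution
from cgstack.errors import DegenerateInputError


def _min_image(delta: np.ndarray, box) -> np.ndarray:
    if box is not None:
        delta = delta - np.round(delta / box) * box
    return delta


def _stacked(cg_traj):
    """(coords (F, N, 3), boxes (F, 3) or None) for any frame iterable."""
    frames = list(cg_traj)
    coords = np.stack([fr.bead_coordinates for fr in frames])
    if frames and frames[0].box is not None:
        boxes = np.stack([fr.box for fr in frames])
    else:
        boxes = None
    return coords, boxes


def measure_bond_series(cg_traj, term: tuple[int, int]) -> np.ndarray:
    """Distance between two beads in every frame (nm)."""
    i, j = term
    coords, boxes = _stacked(cg_traj)
    d = coords[:, j] - coords[:, i]
    if boxes is not None:
        d -= np.round(d / boxes) * boxes
    return np.sqrt((d ** 2).sum(axis=1))


def measure_angle_series(cg_traj, term: tuple[int, int, int]) -> np.ndarray:
    """Angle at the middle bead in every frame (degrees in [0, 180])."""
    i, j, k = term
    coords, boxes = _stacked(cg_traj)
    u = coords[:, i] - coords[:, j]
    v = coords[:, k] - coords[:, j]
    if boxes is not None:
        u -= np.round(u / boxes) * boxes
        v -= np.round(v / boxes) * boxes
    nu = np.sqrt((u ** 2).sum(axis=1))
    nv = np.sqrt((v ** 2).sum(axis=1))
    bad = (nu == 0.0) | (nv == 0.0)
    if np.any(bad):
        raise DegenerateInputError(
            f"zero-length angle arm for term {term} in frame "
            f"{int(np.argmax(bad))}"
        )
    c = np.clip((u * v).sum(axis=1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def _padded_range(samples: np.ndarray) -> tuple[float, float]:
    lo = float(samples.min())
    hi = float(samples.max())
    if hi == lo:
        pad = max(0.05 * abs(lo), 1e-6)
    else:
        pad = 0.05 * (hi - lo)
    return lo - pad, hi + pad


def summarize_distribution(samples, term=None, kind: str = "bond",
                           n_bins: int = 100,
                           range: Optional[tuple[float, float]] = None
                           ) -> BondedDistribution:
    """Summarize samples as mean, unbiased variance and a histogram.

    Default binning is ``n_bins`` uniform bins over [min, max] of the
    samples padded 5% on each side.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DegenerateInputError("cannot summarize an empty sample list")
    if samples.size < 2:
        raise DegenerateInputError("need at least 2 samples for a variance")
    lo, hi = range if range is not None else _padded_range(samples)
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    if int(counts.sum()) != samples.size:
        # samples outside an explicit range: clip into the edge bins so the
        # invariant "counts sum to sample count" holds
        clipped = np.clip(samples, lo, np.nextafter(hi, lo))
        counts, edges = np.histogram(clipped, bins=n_bins, range=(lo, hi))
    return BondedDistribution(
        term=term if term is not None else (),
        kind=kind,
        samples=samples,
        mean=float(samples.mean()),
        variance=float(samples.var(ddof=1)),
        bin_edges=edges,
        counts=counts,
    )


def distribution_divergence(dist_a: BondedDistribution,
                            dist_b: BondedDistribution,
                            n_bins: Optional[int] = None) -> float:
    """Jensen-Shannon divergence (base 2) between two bonded marginals.

    Both distributions are rebinned from their samples onto a shared edge
    set covering both supports, then compared as probability mass per bin.
    The result is symmetric, 0 for identical histograms and 1 for fully
    disjoint supports.
    """
    if dist_a.samples.size == 0 or dist_b.samples.size == 0:
        raise DegenerateInputError("cannot compare an empty distribution")
    if n_bins is None:
        n_bins = max(len(dist_a.counts), len(dist_b.counts))
    pooled = np.concatenate([dist_a.samples, dist_b.samples])
    lo, hi = _padded_range(pooled)
    ca, edges = np.histogram(dist_a.samples, bins=n_bins, range=(lo, hi))
    cb, _ = np.histogram(dist_b.samples, bins=n_bins, range=(lo, hi))
    return jensen_shannon(ca, cb)


def jensen_shannon(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Base-2 JSD of two histograms sharing one edge set."""
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.sum() == 0 or counts_b.sum() == 0:
        raise DegenerateInputError("cannot compare an empty histogram")
    p = counts_a / counts_a.sum()
    q = counts_b / counts_b.sum()
    m = 0.5 * (p + q)
    mask_p = p > 0
    mask_q = q > 0
    jsd = 0.5 * float((p[mask_p] * np.log2(p[mask_p] / m[mask_p])).sum()) \
        + 0.5 * float((q[mask_q] * np.log2(q[mask_q] / m[mask_q])).sum())
    return min(max(jsd, 0.0), 1.0)


def summary_table(distributions: Sequence[BondedDistribution]) -> pd.DataFrame:
    """Tabular per-term summary (term id, kind, mean, variance, n)."""
    return pd.DataFrame(
        {
            "term": ["-".join(map(str, d.term)) for d in distributions],
            "kind": [d.kind for d in distributions],
            "mean": [d.mean for d in distributions],
            "variance": [d.variance for d in distributions],
            "n": [d.n for d in distributions],
        }
    )
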