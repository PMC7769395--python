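"""Recovery of the statistical-uncertainty parameter from dose differences.

Given a noisy calculation and its ground truth, each voxel's dose difference
is expressed as a percent of the local ground-truth dose,

    dD_i = 100 * (D_i(SU) - D_i(0)) / D_i(0),

and binned by the ground-truth dose as a percent of Dmax into 100 intervals
of 1% width.  Under the sqrt-dose Gaussian noise model the per-bin variance
of dD follows a closed form,

    Var(dD | rel dose d%) = SU^2 * 100 / d,

minimal (= SU^2) at the maximum dose and rising hyperbolically toward low
dose — the "asymptote" seen when normalising by small local doses.  Pooling
voxels across plans within each bin and inverting the closed form recovers
the injected SU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grids import DoseGrid

__all__ = [
    "BinnedVariance",
    "VarianceAccumulator",
    "CongruenceError",
    "EstimationError",
    "relative_differences",
    "binned_variance",
    "model_variance",
    "estimate_su",
]

N_BINS = 100  # fixed: 100 intervals of 1% relative dose each


class CongruenceError(ValueError):
    """Noisy and ground-truth grids are not congruent."""


class EstimationError(ValueError):
    """No occupied bins available for SU estimation."""


@dataclass(frozen=True)
class BinnedVariance:
    """Per-relative-dose-interval statistics of pooled dose differences.

    Bins are half-open ``(k-1, k]`` % of Dmax for k = 1..100, so voxels at
    exactly 100% land in the top bin.  ``variance`` holds the sample (n-1)
    variance of the pooled dD values in %^2, NaN where a bin has fewer than
    two voxels.
    """

    bin_edges: np.ndarray   # 101 edges: 0, 1, ..., 100
    counts: np.ndarray      # (100,) voxels per bin
    means: np.ndarray       # (100,) mean dD, %; NaN for empty bins
    variances: np.ndarray   # (100,) sample variance of dD, %^2; NaN below n=2

    def __post_init__(self) -> None:
        if len(self.counts) != N_BINS:
            raise ValueError(f"expected exactly {N_BINS} bins")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def relative_differences(
    noisy: DoseGrid, truth: DoseGrid, min_rel_dose_pct: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel percent dose differences with their relative dose levels.

    Returns ``(dD, rel_dose)`` over the voxels whose ground-truth relative
    dose exceeds ``min_rel_dose_pct`` (% of the single maximum ground-truth
    voxel).  The floor excludes the low-dose region where the percent
    difference diverges as the local dose approaches zero.
    """
    if noisy.shape != truth.shape:
        raise CongruenceError(
            f"grids not congruent: {noisy.shape} vs {truth.shape}"
        )
    dmax = truth.max_dose
    if dmax <= 0:
        raise ValueError("ground truth has no positive dose")
    t = truth.values.ravel()
    n = noisy.values.ravel()
    rel = 100.0 * t / dmax
    keep = rel > min_rel_dose_pct
    dd = 100.0 * (n[keep] - t[keep]) / t[keep]
    return dd, rel[keep]


class VarianceAccumulator:
    """Streaming per-bin pooling of dose differences across many plans.

    Accumulates counts and first/second moments per relative-dose bin so a
    whole cohort can be pooled without holding every voxel in memory; plans
    contribute in proportion to their raw voxel counts.
    """

    def __init__(self) -> None:
        self._counts = np.zeros(N_BINS, dtype=np.int64)
        self._sums = np.zeros(N_BINS, dtype=np.float64)
        self._sqsums = np.zeros(N_BINS, dtype=np.float64)

    def add(self, dd: np.ndarray, rel: np.ndarray) -> "VarianceAccumulator":
        """Add one plan's ``(dD, rel_dose)`` voxel pairs."""
        dd = np.asarray(dd, dtype=np.float64).ravel()
        rel = np.asarray(rel, dtype=np.float64).ravel()
        if dd.shape != rel.shape:
            raise ValueError("dD and rel_dose must have matching lengths")
        # half-open (k-1, k] binning: ceil(rel) - 1 is the 0-based bin index
        idx = np.ceil(rel).astype(np.int64) - 1
        valid = (idx >= 0) & (idx < N_BINS)
        idx, dd = idx[valid], dd[valid]
        self._counts += np.bincount(idx, minlength=N_BINS)
        self._sums += np.bincount(idx, weights=dd, minlength=N_BINS)
        self._sqsums += np.bincount(idx, weights=dd * dd, minlength=N_BINS)
        return self

    @property
    def total(self) -> int:
        return int(self._counts.sum())

    def result(self) -> BinnedVariance:
        counts = self._counts
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, self._sums / np.maximum(counts, 1), np.nan)
            ss = self._sqsums - counts * means**2
            variances = np.where(
                counts >= 2, ss / np.maximum(counts - 1, 1), np.nan
            )
        variances = np.where(counts >= 2, np.maximum(variances, 0.0), np.nan)
        return BinnedVariance(
            bin_edges=np.arange(N_BINS + 1, dtype=np.float64),
            counts=counts.copy(),
            means=means,
            variances=variances,
        )


def binned_variance(
    pairs: tuple[np.ndarray, np.ndarray]
    | Iterable[tuple[np.ndarray, np.ndarray]],
) -> BinnedVariance:
    """Bin pooled dose differences by relative dose and take per-bin variance.

    ``pairs`` is one ``(dD, rel_dose)`` pair or an iterable of them (one per
    plan); voxels are pooled raw across plans so each plan contributes in
    proportion to its voxel count.  Always returns exactly 100 bins covering
    (0, 100] % of Dmax in 1% steps.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2 and np.ndim(pairs[0]) == 1:
        pairs = [pairs]
    acc = VarianceAccumulator()
    for dd, rel in pairs:
        acc.add(dd, rel)
    if acc.total == 0:
        raise ValueError("binned_variance requires at least one (dD, rel) pair")
    return acc.result()


def model_variance(su_percent: float, rel_dose_pct: float) -> float:
    """Theoretical variance of the percent dose difference at a dose level.

    ``SU^2 * 100 / d`` for relative dose d in (0, 100]: SU^2 at the maximum
    dose, diverging toward zero dose.
    """
    if not 0 < rel_dose_pct <= 100:
        raise ValueError(
            f"rel_dose_pct must lie in (0, 100], got {rel_dose_pct}"
        )
    if su_percent < 0:
        raise ValueError("su_percent must be >= 0")
    return su_percent**2 * 100.0 / rel_dose_pct


def estimate_su(binned: BinnedVariance, d_min_pct: float = 50.0) -> float:
    """Invert the variance profile to recover the injected SU.

    Each occupied bin above ``d_min_pct`` yields an SU^2 estimate
    ``variance * d_mid / 100``; these are combined as a count-weighted mean
    and the square root returned.  Exact when fed noiseless model variances;
    consistent under sampling noise as voxel counts grow.
    """
    mids = binned.midpoints
    ok = (mids >= d_min_pct) & (binned.counts >= 2) & np.isfinite(binned.variances)
    if not ok.any():
        raise EstimationError(
            f"no occupied bins at or above {d_min_pct}% relative dose"
        )
    su_sq = binned.variances[ok] * mids[ok] / 100.0
    weights = binned.counts[ok].astype(np.float64)
    return float(np.sqrt(np.sum(su_sq * weights) / np.sum(weights)))
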