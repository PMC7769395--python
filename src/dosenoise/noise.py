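"""Dose-dependent Gaussian noise model for Monte Carlo calculations.

A Monte Carlo dose distribution calculated at statistical uncertainty SU can
be modelled as the noise-free field plus an independent zero-mean Gaussian
error in each voxel whose standard deviation scales with the square root of
the local dose:

    D_i(SU) = D_i(0) + g_i * (SU/100) * Dmax * sqrt(D_i(0) / Dmax)

with g_i i.i.d. standard normal and Dmax the single maximum voxel of the
noise-free field.  SU is therefore the noise standard deviation at the Dmax
voxel, expressed as a percent of Dmax — the interpretation consistent with
the observed variance profile of a commercial TPS, whose "statistical
uncertainty" behaves as a standard deviation, not a variance.

A fixed seed makes injection deterministic, emulating the fixed initial
seed of a TPS whose repeat calculations are bit-identical.  Realizations at
different SU settings are statistically independent here; the nested-history
behaviour of a real engine (a low-SU run extending a high-SU run's
histories) is deliberately not emulated, since pooled-variance analysis does
not depend on cross-SU correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid

__all__ = ["NoiseConfig", "DegenerateInputError", "inject_noise", "achieved_su"]


class DegenerateInputError(ValueError):
    """Noise injection on an all-zero dose grid."""


@dataclass(frozen=True)
class NoiseConfig:
    """Noise-injection settings.

    ``su_percent`` is the requested SU (sigma at Dmax, % of Dmax);
    ``cap_su_percent``, when set, emulates the per-control-point history
    limit of a real engine, under which requests above the cap produce the
    capped calculation (e.g. a 3.00% request yielding the 2.00% result).
    """

    su_percent: float
    seed: int = 0
    cap_su_percent: float | None = None

    def __post_init__(self) -> None:
        if self.su_percent < 0:
            raise ValueError("su_percent must be >= 0")
        if self.cap_su_percent is not None and not self.cap_su_percent > 0:
            raise ValueError("cap_su_percent, when set, must be > 0")


def achieved_su(requested: float, cap_su_percent: float | None = None) -> float:
    """SU actually realised by the engine: the request, ceiling-limited."""
    if requested < 0:
        raise ValueError("requested SU must be >= 0")
    if cap_su_percent is None:
        return requested
    return min(requested, cap_su_percent)


def inject_noise(grid0: DoseGrid, cfg: NoiseConfig) -> DoseGrid:
    """Add statistical noise at the configured SU to a noise-free grid.

    Deterministic in ``(grid0, cfg)``: the same input and seed always yield
    a bit-identical realization.  Zero-dose voxels are left untouched (the
    sqrt scaling vanishes there).  Negative results are clipped to zero, as
    a dose display cannot go negative.
    """
    dmax = grid0.max_dose
    if dmax <= 0:
        raise DegenerateInputError("cannot inject noise into an all-zero grid")
    su = achieved_su(cfg.su_percent, cfg.cap_su_percent)
    if su == 0:
        return grid0
    rng = np.random.default_rng(cfg.seed)
    g = rng.standard_normal(grid0.shape)
    sigma = (su / 100.0) * dmax * np.sqrt(grid0.values / dmax)
    noisy = np.clip(grid0.values + g * sigma, 0.0, None)
    return grid0.with_values(noisy)
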