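"""Synthetic stereotactic-radiotherapy plan generator.

Clinical SRT dose distributions share a characteristic statistical structure:
a small hot target whose maximum dose sits ~130% of the prescription, a
prescription isodose down near ~70% of Dmax, steep exponential fall-off
outside the target, and (for spine) an organ at risk held in a low-dose
trough right next to the target.  This module generates noise-free dose
fields and structure sets with that structure so the downstream noise and
metric analyses have realistic dose-level occupancy to work on, without
modelling beams, fluence or tissue density.

Site conventions (isotropic PTV margin, coverage normalisation):

========  ==========  =============
site      margin      coverage
========  ==========  =============
brain     1 mm        D98 = Rx
lung      5 mm        D98 = Rx
spine     2 mm        D90 = Rx
========  ==========  =============

All geometry is built with Euclidean distance transforms, so "isotropic
growth" means a true Euclidean dilation, not a cubic structuring element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .grids import DoseGrid, StructureMask
from .metrics import dose_at_relative_volume

__all__ = [
    "PlanSpec",
    "GeometryError",
    "DegeneratePlanError",
    "SITE_MARGIN_MM",
    "SITE_COVERAGE_PCT",
    "make_structures",
    "dose_field",
    "normalize_to_coverage",
    "make_plan",
]

SITE_MARGIN_MM: Mapping[str, float] = {"brain": 1.0, "lung": 5.0, "spine": 2.0}
SITE_COVERAGE_PCT: Mapping[str, float] = {"brain": 98.0, "lung": 98.0, "spine": 90.0}

# cord geometry for spine plans (cm)
_CORD_RADIUS_CM = 0.3
_PRV_MARGIN_CM = 0.2          # PRV = cord + 2 mm, matching spine PTV margins
_CORD_CARVE_EXTRA_CM = 0.1    # GTV excludes PRV plus this corridor


class GeometryError(ValueError):
    """Requested structures do not fit inside the dose grid."""


class DegeneratePlanError(ValueError):
    """Plan cannot be normalised (coverage dose is zero)."""


@dataclass(frozen=True)
class PlanSpec:
    """Parameters of one synthetic SRT plan.

    ``hotspot_ratio`` is Dmax/Rx of the noise-free field before coverage
    normalisation (SRT plans run ~1.3); ``falloff_cm`` is the exponential
    fall-off length of the dose outside the target; ``coverage_pct`` and
    ``ptv_margin_mm`` default to the site conventions above.
    """

    site: str
    rx_gy: float = 20.0
    hotspot_ratio: float = 1.3
    gtv_radius_cm: float = 0.75
    ptv_margin_mm: float | None = None
    coverage_pct: float | None = None
    falloff_cm: float = 0.9
    conformity_margin_cm: float = 0.1
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_cm: float = 0.1
    seed: int = 0
    plan_id: str = ""

    def __post_init__(self) -> None:
        if self.site not in SITE_MARGIN_MM:
            raise ValueError(f"unknown site {self.site!r}")
        if self.ptv_margin_mm is None:
            object.__setattr__(self, "ptv_margin_mm", SITE_MARGIN_MM[self.site])
        if self.coverage_pct is None:
            object.__setattr__(self, "coverage_pct", SITE_COVERAGE_PCT[self.site])
        if not self.hotspot_ratio > 1:
            raise ValueError("hotspot_ratio must exceed 1 (SRT inhomogeneity)")
        if not 0 < self.coverage_pct <= 100:
            raise ValueError("coverage_pct must lie in (0, 100]")
        if self.ptv_margin_mm < 0:
            raise ValueError("ptv_margin_mm must be >= 0")
        if not self.falloff_cm > 0:
            raise ValueError("falloff_cm must be > 0")
        if self.conformity_margin_cm < 0:
            raise ValueError("conformity_margin_cm must be >= 0")
        if not self.rx_gy > 0 or not self.gtv_radius_cm > 0:
            raise ValueError("rx_gy and gtv_radius_cm must be > 0")
        if not self.plan_id:
            object.__setattr__(self, "plan_id", f"{self.site}-{self.seed:04d}")


def _coord_grids(shape, spacing_cm):
    """Physical coordinates (cm) of voxel centers along each axis."""
    return [np.arange(n, dtype=np.float64) * spacing_cm for n in shape]


def _dilate(mask: np.ndarray, margin_cm: float, spacing_cm: float) -> np.ndarray:
    """Euclidean dilation: all voxels within margin_cm of the mask."""
    if margin_cm <= 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_cm)
    return dist <= margin_cm + 1e-9


def make_structures(spec: PlanSpec) -> dict[str, StructureMask]:
    """Voxelise the plan's structure set.

    GTV is a sphere at the grid center (for spine, minus a corridor around
    the cord PRV so target and cord never overlap); PTV is the GTV grown
    isotropically by the site margin; spine plans additionally carry a cord
    (axial cylinder beside the target) and PRV (cord + 2 mm).

    Raises :class:`GeometryError` if GTV or PTV touch the grid boundary
    (the cord cylinder is allowed to run the full axial extent).
    """
    s = spec.spacing_cm
    z, y, x = np.meshgrid(*_coord_grids(spec.shape, s), indexing="ij")
    center = tuple(0.5 * (n - 1) * s for n in spec.shape)

    r2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    sphere = r2 <= spec.gtv_radius_cm**2

    structures: dict[str, StructureMask] = {}
    if spec.site == "spine":
        # cord axis parallel to z, offset in +y so its surface grazes the GTV sphere
        cord_offset = spec.gtv_radius_cm + _CORD_RADIUS_CM
        cord_y = center[1] + cord_offset
        d_axis2 = (y - cord_y) ** 2 + (x - center[2]) ** 2
        cord = d_axis2 <= _CORD_RADIUS_CM**2
        prv = _dilate(cord, _PRV_MARGIN_CM, s)
        corridor = _dilate(prv, _CORD_CARVE_EXTRA_CM, s)
        gtv = sphere & ~corridor
        structures["cord"] = StructureMask("cord", cord, s)
        structures["prv"] = StructureMask("prv", prv, s)
    else:
        gtv = sphere

    ptv = _dilate(gtv, spec.ptv_margin_mm / 10.0, s)
    structures["gtv"] = StructureMask("gtv", gtv, s)
    structures["ptv"] = StructureMask("ptv", ptv, s)

    if not gtv.any():
        raise GeometryError(f"{spec.plan_id}: GTV is empty on this grid")
    for name in ("gtv", "ptv"):
        m = structures[name].mask
        if (m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
                or m[:, :, 0].any() or m[:, :, -1].any()):
            raise GeometryError(
                f"{spec.plan_id}: {name.upper()} clipped by the grid boundary"
            )
    return structures


def dose_field(spec: PlanSpec, masks: Mapping[str, StructureMask]) -> DoseGrid:
    """Noise-free SRT-like dose distribution for a structure set.

    The high-dose region conforms to the PTV plus a small conformity
    margin, the way an optimised plan wraps its prescription isodose just
    outside the planning volume (which is what puts clinical Paddick
    indices in the 0.7-1.0 range rather than at 1).  Dose rises from the
    Rx level at the conformity surface through a gentle (~5%) gradient
    across the margin shell — an optimised plan never holds a mathematically
    flat shell at exactly the prescription — then ramps smoothly inside the
    GTV up to ``rx * hotspot_ratio`` with a flat (zero-gradient) top at the
    deepest interior point, as a blurred physical hotspot has.  Outside the
    conformity surface the dose decays as ``exp(-d / falloff_cm)`` of the
    Euclidean distance to it.  A smooth seeded random modulation (~3% RMS,
    correlation length ~1 cm) perturbs the field so distinct seeds give
    distinct but equally plausible plans.  For spine plans a multiplicative
    trough toward the cord axis keeps the cord in a low-dose region beside
    the hot target.

    Isodose volumes nest by construction (higher levels are subsets), the
    Dmax voxel lies inside the GTV, and after coverage normalisation the
    prescription isodose sits in the SRT-typical 60-85% band of Dmax.
    """
    s = spec.spacing_cm
    gtv = masks["gtv"].mask
    ptv = masks["ptv"].mask
    rx = spec.rx_gy
    edge_delta = 0.07  # fractional dose rise across the plateau shell
    ramp_cm = 0.18     # penumbra-like length of that rise

    plateau = _dilate(ptv, spec.conformity_margin_cm, s)
    d_out = ndimage.distance_transform_edt(~plateau, sampling=s)
    d_shell = ndimage.distance_transform_edt(plateau, sampling=s)
    d_in = ndimage.distance_transform_edt(gtv, sampling=s)
    d_in_max = d_in.max()

    # the shell ramp is linear over a fixed penumbra-like length — zero
    # curvature where the profile crosses the Rx level, since curvature
    # right at the threshold biases isodose volumes under block averaging;
    # the hotspot ramp u(2 - u) has finite slope at the GTV surface and a
    # flat top, a smooth rounded peak instead of a cusp
    t = np.clip(d_shell / ramp_cm, 0.0, 1.0)
    u = d_in / d_in_max if d_in_max > 0 else np.zeros_like(d_in)
    inside = (
        1.0
        + edge_delta * t
        + (spec.hotspot_ratio - 1.0 - edge_delta) * u * (2.0 - u)
    )
    # outside decay exp(-(k0 d + (d/f)^2)): the linear term continues the
    # shell ramp's slope through the prescription isodose, the quadratic
    # term gives a penumbra-like far fall-off
    k0 = edge_delta / ramp_cm
    dose = np.where(
        plateau,
        rx * inside,
        rx * np.exp(-(k0 * d_out + (d_out / spec.falloff_cm) ** 2)),
    )

    # smooth multiplicative modulation: white noise blurred to ~1 cm scale
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.shape)
    smooth = ndimage.gaussian_filter(white, sigma=1.0 / s, mode="nearest")
    rms = smooth.std()
    if rms > 0:
        smooth = smooth / rms
    dose = dose * (1.0 + 0.03 * smooth)

    if spec.site == "spine":
        z, y, x = np.meshgrid(*_coord_grids(spec.shape, s), indexing="ij")
        center = tuple(0.5 * (n - 1) * s for n in spec.shape)
        cord_y = center[1] + spec.gtv_radius_cm + _CORD_RADIUS_CM
        d_axis = np.sqrt((y - cord_y) ** 2 + (x - center[2]) ** 2)
        d_cord = np.maximum(d_axis - _CORD_RADIUS_CM, 0.0)
        # trough: down to 45% of local dose at the cord surface, relaxing
        # over ~6 mm — the dose gradient a spine plan holds across the cord
        trough = 1.0 - 0.55 * np.exp(-((d_cord / 0.6) ** 2))
        dose = dose * np.where(gtv, 1.0, trough)

    dose = np.clip(dose, 0.0, None)
    # guarantee the global maximum sits inside the GTV
    if not gtv[np.unravel_index(np.argmax(dose), dose.shape)]:
        outside_max = dose[~gtv].max()
        inside_max = dose[gtv].max()
        dose[~gtv] *= 0.999 * inside_max / outside_max
    return DoseGrid(values=dose, spacing_cm=s, plan_id=spec.plan_id)


def normalize_to_coverage(
    grid: DoseGrid, ptv: StructureMask, rx_gy: float, coverage_pct: float
) -> DoseGrid:
    """Uniformly rescale a plan so the PTV coverage dose equals the Rx.

    After scaling, the dose received by ``coverage_pct`` % of the PTV equals
    ``rx_gy`` exactly — the clinical normalisation rule (D98 = Rx for
    brain/lung, D90 = Rx for spine).  Scaling is multiplicative, hence
    idempotent and commuting with any further uniform scaling.
    """
    if ptv.voxel_count == 0:
        raise DegeneratePlanError("PTV is empty")
    d_cov = dose_at_relative_volume(grid, ptv, coverage_pct)
    if d_cov <= 0:
        raise DegeneratePlanError(
            f"coverage dose at {coverage_pct}% of the PTV is zero"
        )
    return grid.with_values(grid.values * (rx_gy / d_cov))


def make_plan(spec: PlanSpec) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Generate a complete normalised noise-free plan.

    Convenience composition: structures, dose field, coverage normalisation.
    Bit-reproducible from ``spec`` (including its seed).
    """
    masks = make_structures(spec)
    grid = dose_field(spec, masks)
    grid = normalize_to_coverage(grid, masks["ptv"], spec.rx_gy, spec.coverage_pct)
    return grid, masks
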