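"""DVH metrics and plan-quality indices.

Everything here is computed by whole-voxel counting on the native lattice:
a structure's volume is (voxel count) x spacing^3, dose-at-volume metrics
are read off the descending-sorted voxel doses with no sub-voxel
interpolation, and isodose volumes are voxel counts.  This keeps every
metric bit-reproducible and consistent with reasoning about how many
voxels a reporting volume contains at a given dose voxel size.

Metrics
-------
* cumulative DVH curve;
* dose at relative volume D_v% (coverage metrics such as D98/D90);
* dose at absolute volume D_vcc (near-maximum dose, e.g. D0.035cc — the
  ICRU-style robust surrogate for a point maximum);
* mean dose;
* Paddick conformity index  PCI = TVPIV^2 / (TV x VRI);
* gradient index            GI  = VR50 / VRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DoseGrid, StructureMask

__all__ = [
    "DVHCurve",
    "MetricReport",
    "StructureError",
    "VolumeError",
    "UndefinedIndexError",
    "cumulative_dvh",
    "dose_at_relative_volume",
    "dose_at_absolute_volume",
    "mean_dose",
    "paddick_ci",
    "gradient_index",
    "compute_report",
    "NEAR_MAX_VOLUMES_CC",
]

#: the two near-maximum reporting volumes compared throughout (cc)
NEAR_MAX_VOLUMES_CC = (0.035, 0.100)


class StructureError(ValueError):
    """Operation on an empty structure mask."""


class VolumeError(ValueError):
    """Requested absolute volume exceeds the region volume."""


class UndefinedIndexError(ValueError):
    """Index denominator volume is empty (e.g. no voxel reaches the Rx)."""


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``rel_volume[i]`` is the percentage of the structure receiving at least
    ``dose_axis[i]`` Gy; it is monotone non-increasing and starts at 100%.
    """

    dose_axis: np.ndarray
    rel_volume: np.ndarray


def _masked(grid: DoseGrid, mask: StructureMask | None) -> np.ndarray:
    if mask is None:
        return grid.values.ravel()
    if mask.mask.shape != grid.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match grid {grid.shape}"
        )
    return grid.values[mask.mask]


def cumulative_dvh(
    grid: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.05
) -> DVHCurve:
    """Cumulative DVH of a structure by voxel counting."""
    doses = _masked(grid, mask)
    if doses.size == 0:
        raise StructureError(f"structure {mask.name!r} is empty")
    if not bin_width_gy > 0:
        raise ValueError("bin_width_gy must be > 0")
    top = doses.max()
    n_bins = int(np.ceil(top / bin_width_gy)) + 1
    axis = np.arange(n_bins + 1) * bin_width_gy
    sorted_doses = np.sort(doses)
    # fraction of voxels with dose >= level
    idx = np.searchsorted(sorted_doses, axis, side="left")
    rel = 100.0 * (doses.size - idx) / doses.size
    rel[0] = 100.0  # volume at dose 0 is the whole structure by definition
    return DVHCurve(dose_axis=axis, rel_volume=rel)


def dose_at_relative_volume(
    grid: DoseGrid, mask: StructureMask, v_pct: float
) -> float:
    """Largest dose D such that >= v_pct % of the structure receives >= D.

    Sorted-voxel definition with no interpolation: with n voxels the answer
    is the ceil(n * v/100)-th highest voxel dose.
    """
    doses = _masked(grid, mask)
    if doses.size == 0:
        raise StructureError(f"structure {mask.name!r} is empty")
    if not 0 < v_pct <= 100:
        raise ValueError(f"v_pct must lie in (0, 100], got {v_pct}")
    k = int(np.ceil(doses.size * v_pct / 100.0))
    k = min(max(k, 1), doses.size)
    return float(np.partition(doses, doses.size - k)[doses.size - k])


def dose_at_absolute_volume(
    grid: DoseGrid, mask: StructureMask | None, v_cc: float
) -> float:
    """Near-maximum dose: dose to the hottest ``v_cc`` of a region.

    Voxels are sorted descending; the result is the dose of the voxel at
    which the cumulative volume first reaches or exceeds ``v_cc``
    (whole-voxel convention).  ``mask=None`` uses the whole grid (plan-level
    near maximum).
    """
    doses = _masked(grid, mask)
    if doses.size == 0:
        raise StructureError("region is empty")
    if not v_cc > 0:
        raise ValueError(f"v_cc must be > 0, got {v_cc}")
    vox_cc = grid.voxel_volume_cc
    if v_cc > doses.size * vox_cc + 1e-12:
        raise VolumeError(
            f"requested {v_cc} cc exceeds region volume {doses.size * vox_cc:.6g} cc"
        )
    k = int(np.ceil(v_cc / vox_cc - 1e-12))
    k = min(max(k, 1), doses.size)
    return float(np.partition(doses, doses.size - k)[doses.size - k])


def mean_dose(grid: DoseGrid, mask: StructureMask) -> float:
    """Arithmetic mean dose over a structure."""
    doses = _masked(grid, mask)
    if doses.size == 0:
        raise StructureError(f"structure {mask.name!r} is empty")
    return float(doses.mean())


def paddick_ci(grid: DoseGrid, tv_mask: StructureMask, rx_gy: float) -> float:
    """Paddick conformity index of the prescription isodose to a target.

    PCI = TVPIV^2 / (TV x VRI) where TVPIV is the target volume covered by
    the Rx isodose, TV the target volume and VRI the Rx isodose volume; 1 is
    perfect conformity.  Returns 0 when no target voxel reaches the Rx
    (including the fully degenerate case VRI = 0).
    """
    if tv_mask.voxel_count == 0:
        raise StructureError("target volume is empty")
    if not rx_gy > 0:
        raise ValueError("rx_gy must be > 0")
    if tv_mask.mask.shape != grid.shape:
        raise ValueError("target mask does not match grid shape")
    piv = grid.values >= rx_gy
    tv_piv = int((piv & tv_mask.mask).sum())
    if tv_piv == 0:
        return 0.0
    vri = int(piv.sum())
    return tv_piv**2 / (tv_mask.voxel_count * vri)


def gradient_index(grid: DoseGrid, rx_gy: float) -> float:
    """Gradient index: V(Rx/2) / V(Rx), measuring dose fall-off steepness.

    Always >= 1 since the Rx isodose region is contained in the half-Rx one.
    """
    if not rx_gy > 0:
        raise ValueError("rx_gy must be > 0")
    vri = int((grid.values >= rx_gy).sum())
    if vri == 0:
        raise UndefinedIndexError("no voxel reaches the prescription dose")
    vr50 = int((grid.values >= rx_gy / 2.0).sum())
    return vr50 / vri


@dataclass(frozen=True)
class MetricReport:
    """All evaluated metrics of one calculated dose distribution.

    ``metrics`` maps metric names to values; ``deviations`` maps the same
    names to deviations from the plan's ground truth — percent of the
    ground-truth value for dose metrics, absolute difference for the
    dimensionless indices (PCI, GI).
    """

    plan_id: str
    site: str
    dvs_cm: float
    su_percent: float
    metrics: dict[str, float]
    deviations: dict[str, float] = field(default_factory=dict)


#: metrics whose deviations are reported as absolute differences
_ABSOLUTE_DEVIATION_METRICS = frozenset({"pci", "gi"})


def compute_report(
    grid: DoseGrid,
    masks: dict[str, StructureMask],
    *,
    rx_gy: float,
    coverage_pct: float,
    site: str,
    su_percent: float,
    reference: MetricReport | None = None,
) -> MetricReport:
    """Evaluate the full metric panel for one calculation.

    Records the plan near-maximum dose at both 0.035 cc and 0.100 cc, the
    PTV coverage dose, the GTV mean dose, cord and PRV near-maximum doses
    for spine plans (both reporting volumes), the Paddick conformity index
    of the PTV and the gradient index.  When ``reference`` (the same plan's
    ground-truth report) is given, deviations are filled in: percent of the
    reference for doses, absolute difference for PCI and GI.
    """
    m: dict[str, float] = {}
    for v_cc in NEAR_MAX_VOLUMES_CC:
        m[f"plan_near_max_{v_cc:.3f}cc"] = dose_at_absolute_volume(grid, None, v_cc)
    m["ptv_coverage"] = dose_at_relative_volume(grid, masks["ptv"], coverage_pct)
    m["gtv_mean"] = mean_dose(grid, masks["gtv"])
    if site == "spine":
        for organ in ("cord", "prv"):
            for v_cc in NEAR_MAX_VOLUMES_CC:
                m[f"{organ}_near_max_{v_cc:.3f}cc"] = dose_at_absolute_volume(
                    grid, masks[organ], v_cc
                )
    m["pci"] = paddick_ci(grid, masks["ptv"], rx_gy)
    m["gi"] = gradient_index(grid, rx_gy)

    deviations: dict[str, float] = {}
    if reference is not None:
        for name, value in m.items():
            ref = reference.metrics[name]
            if name in _ABSOLUTE_DEVIATION_METRICS:
                deviations[name] = value - ref
            else:
                deviations[name] = 100.0 * (value - ref) / ref if ref != 0 else np.nan
    return MetricReport(
        plan_id=grid.plan_id,
        site=site,
        dvs_cm=grid.spacing_cm,
        su_percent=su_percent,
        metrics=m,
        deviations=deviations,
    )
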