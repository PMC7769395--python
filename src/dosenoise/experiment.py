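"""Desk-scale orchestration of the full noise study.

The study design: a cohort of synthetic SRT plans (default 10 brain, 10
lung, 10 spine), each with a single high-resolution ground truth plus
recalculations at every combination of two dose voxel sizes (0.1 and
0.2 cm) and five statistical-uncertainty settings (0.50%, 0.75%, 1.00%,
1.50%, 2.00%) — 11 calculations per plan, 330 dose distributions for the
default cohort.  For every noisy calculation the full metric panel is
evaluated and its deviation from the plan's ground truth recorded; the
deviations are then summarised per (metric, DVS, SU) cell with box-plot
statistics (median, quartiles, 1.5 x IQR outliers), and voxel differences
of the fine-DVS arm are pooled across plans for the binned-variance
analysis that recovers the injected SU.

A simple calculation-time scaling law accompanies the study: the time to
run a Monte Carlo calculation scales as DVS^-3 (volumetric voxel count)
and SU^-2 (histories needed, since SU falls as 1/sqrt(N)), so only time
*ratios* between settings are predicted, never absolute times.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import DoseGrid, StructureMask, downsample, downsample_mask
from .metrics import MetricReport, compute_report
from .noise import NoiseConfig, inject_noise
from .su_estimation import (
    BinnedVariance,
    VarianceAccumulator,
    estimate_su,
    relative_differences,
)
from .synthetic import SITE_COVERAGE_PCT, PlanSpec, make_plan

__all__ = [
    "StudyConfig",
    "CalcEntry",
    "DeviationSummary",
    "StudyResult",
    "TimeModel",
    "default_cohort",
    "build_manifest",
    "run_study",
    "summarize",
    "time_ratio",
    "SUMMARY_METRICS",
]

#: ground-truth SU setting emulated in 'emulated' mode (% of Dmax)
GROUND_TRUTH_SU = 0.15

#: metric names summarised per (dvs, su) cell; cord_prv_near_max pools the
#: cord and PRV near-maximum deviations of spine plans (two points per plan)
SUMMARY_METRICS = (
    "plan_near_max_0.035cc",
    "plan_near_max_0.100cc",
    "ptv_coverage",
    "gtv_mean",
    "pci",
    "gi",
    "cord_prv_near_max",
)

# per-site GTV radius bands (cm): brain PTVs land below 10 cc, lung and
# spine PTVs above, matching the small-target mix of an SRT cohort
_SITE_RADIUS_CM = {"brain": (0.5, 0.9), "lung": (0.9, 1.2), "spine": (1.3, 1.5)}
_SITE_RX_GY = {"brain": 21.0, "lung": 54.0, "spine": 24.0}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run."""

    n_brain: int = 10
    n_lung: int = 10
    n_spine: int = 10
    dvs_arms_cm: tuple[float, ...] = (0.1, 0.2)
    su_arms_percent: tuple[float, ...] = (0.50, 0.75, 1.00, 1.50, 2.00)
    ground_truth_mode: str = "exact"  # 'exact' or 'emulated'
    master_seed: int = 0
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_cm: float = 0.1
    min_rel_dose_pct: float = 0.5

    def __post_init__(self) -> None:
        if not self.dvs_arms_cm or not self.su_arms_percent:
            raise ValueError("DVS and SU arms must be non-empty")
        if self.ground_truth_mode not in {"exact", "emulated"}:
            raise ValueError(f"unknown ground_truth_mode {self.ground_truth_mode!r}")
        for dvs in self.dvs_arms_cm:
            ratio = dvs / self.spacing_cm
            if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
                raise ValueError(
                    f"DVS arm {dvs} cm is not an integer multiple of the "
                    f"generation spacing {self.spacing_cm} cm"
                )

    @property
    def n_plans(self) -> int:
        return self.n_brain + self.n_lung + self.n_spine


@dataclass(frozen=True)
class CalcEntry:
    """One row of the calculation manifest."""

    plan_id: str
    site: str
    dvs_cm: float
    su_percent: float
    seed: int
    is_ground_truth: bool = False


@dataclass(frozen=True)
class DeviationSummary:
    """Box-plot statistics of one metric's deviations in one (DVS, SU) cell.

    Median and quartiles use linear interpolation between order statistics;
    outliers are points more than 1.5 x IQR beyond the quartile boundaries.
    """

    metric: str
    dvs_cm: float
    su_percent: float
    median: float
    q25: float
    q75: float
    outliers: tuple[float, ...]
    n: int

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


@dataclass(frozen=True)
class TimeModel:
    """Calculation-time scaling law Tc = k * SU^-2 * DVS^-3.

    ``k`` carries the (hardware-dependent) time units; all ratio predictions
    are independent of it.
    """

    k: float = 1.0

    def predict(self, dvs_cm: float, su_percent: float) -> float:
        if not (dvs_cm > 0 and su_percent > 0):
            raise ValueError("dvs_cm and su_percent must be > 0")
        return self.k / (su_percent**2 * dvs_cm**3)


def time_ratio(dvs_a: float, su_a: float, dvs_b: float, su_b: float) -> float:
    """Predicted calculation-time ratio Tc(a) / Tc(b) between two settings.

    Halving the DVS costs 8x (voxel count), halving the SU costs 4x
    (histories); combined, (su_b/su_a)^2 * (dvs_b/dvs_a)^3.
    """
    for v in (dvs_a, su_a, dvs_b, su_b):
        if not v > 0:
            raise ValueError("all settings must be > 0")
    return (su_b / su_a) ** 2 * (dvs_b / dvs_a) ** 3


def derive_seed(master_seed: int, *parts: object) -> int:
    """Stable per-entry RNG seed below 2^31, from hashed identifiers."""
    key = "|".join([str(master_seed), *(str(p) for p in parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def default_cohort(cfg: StudyConfig) -> list[PlanSpec]:
    """Build the cohort's plan specifications, reproducible from the config.

    Per-plan target radii, hotspot ratios and fall-off lengths are drawn
    from seeded site-specific bands so each plan is distinct but the cohort
    is bit-reproducible from the master seed.
    """
    specs: list[PlanSpec] = []
    counts = {"brain": cfg.n_brain, "lung": cfg.n_lung, "spine": cfg.n_spine}
    for site, n in counts.items():
        lo, hi = _SITE_RADIUS_CM[site]
        for i in range(n):
            seed = derive_seed(cfg.master_seed, "plan", site, i)
            rng = np.random.default_rng(seed)
            specs.append(
                PlanSpec(
                    site=site,
                    rx_gy=_SITE_RX_GY[site],
                    hotspot_ratio=float(rng.uniform(1.25, 1.40)),
                    gtv_radius_cm=float(rng.uniform(lo, hi)),
                    falloff_cm=float(rng.uniform(0.7, 1.1)),
                    shape=cfg.shape,
                    spacing_cm=cfg.spacing_cm,
                    seed=seed,
                    plan_id=f"{site}-{i:02d}",
                )
            )
    return specs


def build_manifest(cfg: StudyConfig) -> list[CalcEntry]:
    """Expand the study config into the list of calculations.

    One ground-truth entry per plan plus one entry per (DVS, SU) cell:
    the default two DVS arms and five SU arms give 11 calculations per plan
    and 330 for the default 30-plan cohort.
    """
    entries: list[CalcEntry] = []
    gt_su = GROUND_TRUTH_SU if cfg.ground_truth_mode == "emulated" else 0.0
    for spec in default_cohort(cfg):
        entries.append(
            CalcEntry(
                plan_id=spec.plan_id,
                site=spec.site,
                dvs_cm=cfg.spacing_cm,
                su_percent=gt_su,
                seed=derive_seed(cfg.master_seed, spec.plan_id, "gt"),
                is_ground_truth=True,
            )
        )
        for dvs in cfg.dvs_arms_cm:
            for su in cfg.su_arms_percent:
                entries.append(
                    CalcEntry(
                        plan_id=spec.plan_id,
                        site=spec.site,
                        dvs_cm=dvs,
                        su_percent=su,
                        seed=derive_seed(cfg.master_seed, spec.plan_id, dvs, su),
                    )
                )
    return entries


def summarize(
    values: Sequence[float],
    *,
    metric: str = "",
    dvs_cm: float = float("nan"),
    su_percent: float = float("nan"),
) -> DeviationSummary:
    """Box-plot summary of a list of deviations.

    Quartiles by linear interpolation between order statistics
    (numpy's default percentile convention); outliers are values beyond
    1.5 x IQR from the quartile boundaries.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("summarize requires at least one value")
    q25, med, q75 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    outliers = tuple(float(v) for v in arr[(arr < lo) | (arr > hi)])
    return DeviationSummary(
        metric=metric,
        dvs_cm=dvs_cm,
        su_percent=su_percent,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        outliers=outliers,
        n=int(arr.size),
    )


@dataclass(frozen=True)
class StudyResult:
    """Everything one study run produces."""

    config: StudyConfig
    manifest: list[CalcEntry]
    reports: list[MetricReport]
    summaries: list[DeviationSummary]
    pooled_variance: dict[float, BinnedVariance]  # per SU, fine-DVS arm
    su_estimates: dict[float, float]
    plan_info: dict[str, dict]

    def summary(self, metric: str, dvs_cm: float, su_percent: float) -> DeviationSummary:
        for s in self.summaries:
            if (
                s.metric == metric
                and np.isclose(s.dvs_cm, dvs_cm)
                and np.isclose(s.su_percent, su_percent)
            ):
                return s
        raise KeyError(f"no summary for {(metric, dvs_cm, su_percent)}")


def _near_max_cc_for_dvs(dvs_cm: float) -> float:
    """Reporting volume for cord/PRV near-max: 0.035 cc at fine DVS,
    0.100 cc at 0.2 cm and coarser, where 0.035 cc holds too few voxels."""
    return 0.035 if dvs_cm < 0.15 else 0.100


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the whole pipeline for every manifest entry.

    Per plan: generate and normalise the noise-free field, fix the ground
    truth (exact field, or a 0.15% realization in 'emulated' mode), derive
    each DVS arm by block-averaging the noise-free field, inject noise per
    (DVS, SU) cell, evaluate the metric panel and its deviations from the
    plan's fine-DVS ground truth.  Finally summarise deviations per
    (metric, DVS, SU) cell and pool the fine-DVS voxel differences across
    plans into the binned-variance analysis, one pooled profile and one
    recovered SU per SU arm.

    Deterministic: two runs with the same config are bit-identical.
    """
    manifest = build_manifest(cfg)
    specs = default_cohort(cfg)
    fine_dvs = cfg.spacing_cm

    reports: list[MetricReport] = []
    plan_info: dict[str, dict] = {}
    accumulators: dict[float, VarianceAccumulator] = {
        su: VarianceAccumulator() for su in cfg.su_arms_percent
    }

    for spec in specs:
        grid0, masks = make_plan(spec)
        if cfg.ground_truth_mode == "emulated":
            gt_seed = derive_seed(cfg.master_seed, spec.plan_id, "gt")
            gt_grid = inject_noise(grid0, NoiseConfig(GROUND_TRUTH_SU, seed=gt_seed))
            gt_su = GROUND_TRUTH_SU
        else:
            gt_grid = grid0
            gt_su = 0.0
        coverage = spec.coverage_pct
        gt_report = compute_report(
            gt_grid, masks, rx_gy=spec.rx_gy, coverage_pct=coverage,
            site=spec.site, su_percent=gt_su,
        )
        reports.append(gt_report)
        plan_info[spec.plan_id] = {
            "site": spec.site,
            "rx_gy": spec.rx_gy,
            "ptv_cc": masks["ptv"].volume_cc,
            "gtv_cc": masks["gtv"].volume_cc,
            "coverage_pct": coverage,
        }

        for dvs in cfg.dvs_arms_cm:
            factor = round(dvs / cfg.spacing_cm)
            arm_grid0 = downsample(grid0, factor)
            arm_masks = {
                name: downsample_mask(m, factor) for name, m in masks.items()
            }
            for su in cfg.su_arms_percent:
                seed = derive_seed(cfg.master_seed, spec.plan_id, dvs, su)
                noisy = inject_noise(arm_grid0, NoiseConfig(su, seed=seed))
                reports.append(
                    compute_report(
                        noisy, arm_masks, rx_gy=spec.rx_gy,
                        coverage_pct=coverage, site=spec.site, su_percent=su,
                        reference=gt_report,
                    )
                )
                if factor == 1:
                    dd, rel = relative_differences(
                        noisy, gt_grid, cfg.min_rel_dose_pct
                    )
                    accumulators[su].add(dd, rel)

    summaries = _summarize_cells(cfg, reports)
    pooled = {su: acc.result() for su, acc in accumulators.items()}
    su_estimates = {su: estimate_su(bv) for su, bv in pooled.items()}
    return StudyResult(
        config=cfg,
        manifest=manifest,
        reports=reports,
        summaries=summaries,
        pooled_variance=pooled,
        su_estimates=su_estimates,
        plan_info=plan_info,
    )


def _summarize_cells(
    cfg: StudyConfig, reports: list[MetricReport]
) -> list[DeviationSummary]:
    summaries: list[DeviationSummary] = []
    noisy = [r for r in reports if r.deviations]
    for dvs in cfg.dvs_arms_cm:
        cc = _near_max_cc_for_dvs(dvs)
        for su in cfg.su_arms_percent:
            cell = [
                r for r in noisy
                if np.isclose(r.dvs_cm, dvs) and np.isclose(r.su_percent, su)
            ]
            if not cell:
                continue
            for metric in SUMMARY_METRICS:
                if metric == "cord_prv_near_max":
                    values = [
                        r.deviations[f"{organ}_near_max_{cc:.3f}cc"]
                        for r in cell if r.site == "spine"
                        for organ in ("cord", "prv")
                    ]
                else:
                    values = [
                        r.deviations[metric] for r in cell if metric in r.deviations
                    ]
                if values:
                    summaries.append(
                        summarize(values, metric=metric, dvs_cm=dvs, su_percent=su)
                    )
    return summaries
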