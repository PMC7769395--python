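# Methods

## Noise model

A Monte Carlo dose calculation at statistical uncertainty SU is modelled as

    D_i(SU) = D_i(0) + g_i · (SU/100) · D_max · √(D_i(0)/D_max),

with independent standard-normal deviates `g_i` and `D_max` the single
maximum voxel of the noise-free field (no volume qualifier). SU is
interpreted as a **standard deviation**, not a variance: the empirical
variance profile of commercial engines sits at SU² at the maximum dose,
which is only consistent with the standard-deviation reading. Noise is
injected deterministically from a seed, emulating engines whose repeat
calculations are bit-identical. Negative results are clipped at zero (a
dose display cannot go negative); with the default low-dose floor of the
variance analysis (0.5% of D_max) the clipping probability in any analysed
voxel is below ~1e-4 and has no measurable effect on the recovered SU.

Deliberately *not* emulated: the nested-history behaviour of real engines
(a low-SU calculation reusing the high-SU calculation's initial histories).
Realizations at different SU settings are independent here; the
pooled-variance analysis is insensitive to cross-SU correlation, but
cell-to-cell differences of cohort medians carry independent sampling noise
that nested histories would partially cancel. The per-control-point history
cap of real engines is available only as an optional hard ceiling
(`cap_su_percent`), under which a request above the cap reproduces the
capped calculation exactly.

## Variance analysis and SU recovery

Voxel differences are taken as a percent of the local ground-truth dose and
binned by ground-truth relative dose into 100 half-open intervals
`(k-1, k]` % of D_max (the half-open choice puts exactly-100% voxels in the
top bin; edge handling is otherwise immaterial). Bins pool raw voxels
across plans, so plans contribute by voxel count. Sample (n−1) variances
are used; bins with fewer than two voxels are flagged NaN. Voxels below
0.5% relative dose are excluded — the percent-difference normalisation
diverges as the local dose approaches zero. The estimator inverts the
closed form Var(ΔD|d) = SU²·100/d as a count-weighted mean of
`variance · d_mid / 100` over occupied bins at or above 50% relative dose
and returns its square root; it is exact on noiseless model inputs and
recovers injected SU to ~0.1% relative when ~10⁶ voxels are pooled.

When validating the per-bin variance law statistically, the expected value
per bin is the occupancy-weighted mean of the per-voxel model (the exact
consequence of the noise law), not the model at the bin midpoint: midpoint
evaluation adds a convexity bias of up to ~4% in low bins, larger than the
sampling standard error at 10³ voxels.

## Metrics

All volumes are voxel counts times the cubic voxel volume; all
dose-at-volume metrics are read off descending-sorted voxel doses with no
sub-voxel interpolation (dose-at-relative-volume v% is the ⌈n·v/100⌉-th
highest voxel; dose-at-absolute-volume v_cc is the dose at which the
cumulative descending volume first reaches v_cc). This whole-voxel
convention keeps every metric bit-reproducible and matches the voxel-count
reasoning that explains DVS sensitivity: 0.035 cc holds 35 voxels at 0.1 cm
but only 4–5 at 0.2 cm, so a single noisy voxel moves the coarse-grid
near-maximum far more. Both near-maximum reporting volumes (0.035 and
0.100 cc) are always recorded; cord/PRV summaries default to 0.035 cc on
the fine grid and 0.100 cc at 0.2 cm, where the smaller volume is too few
voxels to be robust. The Paddick index uses the PTV as the target volume
and returns 0 when no target voxel reaches the prescription; the gradient
index is undefined (error) when nothing reaches the prescription.

## Synthetic plan generator

The generator replaces a clinical plan cohort. It emulates the *statistical
structure* of SRT dose distributions — the features the noise analysis is
sensitive to — not beams or tissue:

- **Structures.** GTV: sphere at the grid center (spine: sphere minus a
  corridor one millimetre beyond the cord PRV, reproducing a cord in a
  low-dose notch beside a hot target). PTV: Euclidean dilation of the GTV
  by the site margin (brain 1 mm, lung 5 mm, spine 2 mm). Spine adds an
  axial cord cylinder (radius 3 mm) and a PRV = cord + 2 mm. Dilations use
  the Euclidean distance transform (true isotropic growth).
- **Dose field.** An Rx-level region conforms to the PTV plus a 1 mm
  conformity margin — optimised plans wrap the prescription isodose just
  outside the PTV, which is what puts Paddick indices in the clinical
  0.7–1.0 range. Within that region the dose rises linearly by 7% over a
  fixed 1.8 mm penumbra-like length (linear, so the profile has no
  curvature where it crosses the Rx level: curvature right at the threshold
  biases isodose volumes under block averaging), then ramps smoothly inside
  the GTV to `hotspot_ratio × Rx` (default 1.3) with a flat top — a blurred
  physical hotspot, not a distance-transform cone cusp, which would
  artificially suppress the near-maximum noise selection bias under study.
  Outside, dose decays as `exp(−(k₀d + (d/f)²))` of the distance d to the
  conformity surface (slope-continuous at the prescription isodose;
  fall-off length f defaults to 0.9 cm). A seeded smooth multiplicative
  modulation (3% RMS, ~1 cm correlation length) makes plans distinct across
  seeds. Spine plans apply a multiplicative trough toward the cord axis
  (floor 45% at the cord surface, relaxing over 6 mm — the gradient a spine
  plan holds across the cord).
- **Normalisation.** Each plan is scaled so the PTV coverage dose equals
  the prescription exactly: D98 = Rx for brain and lung, D90 = Rx for
  spine. After normalisation the prescription isodose sits at 60–85% of
  D_max and default brain plans keep D_max/Rx within 1.2–1.5.
- **Cohort.** 10 plans per site; per-plan GTV radii are drawn from
  site bands (brain 0.5–0.9 cm, lung 0.9–1.2 cm, spine 1.3–1.5 cm) so brain
  PTVs fall below 10 cc and lung/spine PTVs above, with hotspot ratios
  1.25–1.40 and fall-off lengths 0.7–1.1 cm. Everything is bit-reproducible
  from the master seed via stable hashing of (seed, plan, DVS, SU).

What the generator does **not** reproduce: fluence/beam geometry, tissue
heterogeneity (lung/bone density affects MC accuracy, not the noise
statistics analysed here), spatially correlated noise, and the
plan-to-plan diversity of clinical anatomies. Passing tests therefore
demonstrate the noise-propagation mechanics on realistic dose-level
occupancy, not agreement with any clinical cohort's deviation magnitudes.

## Study design

Each plan is generated at 0.1 cm spacing on a 96³ lattice (9.6 cm cube —
inside the 64³–128³ band where the full 30-plan study runs in about a
minute on one CPU). The ground truth defaults to the exact noise-free
field; an `emulated` mode instead injects 0.15% noise at the fine spacing,
mirroring the convention that a very-low-SU calculation is treated as
noise-free. The 0.2 cm arm is derived by 2× block volume-averaging of the
noise-free field (mean-preserving; masks are re-voxelised by majority
occupancy), and noise is injected *after* downsampling, emulating separate
engine runs per DVS. Deviations of every noisy arm are taken against the
fine-grid ground truth, so coarse-arm deviations contain both noise and
partial-volume components, as in a real DVS comparison. Box-plot summaries
use linear interpolation between order statistics for the quartiles and
flag outliers beyond 1.5×IQR from the quartile boundaries. Coverage
deviations are percent changes of the coverage *dose*; PCI and GI
deviations are absolute index differences; all other dose metrics are
percent of the ground-truth value.

## Numerical choices

- Non-divisible lattice shapes error under strict resampling; a lenient
  flag crops trailing voxels and logs the cropped extent.
- Ties in dose-at-volume metrics resolve by dose value only (voxel order
  is irrelevant); an epsilon of 1e-12 cc guards the exact-multiple case of
  the cumulative-volume threshold.
- The NRRD container stores float32 lattices; DICOM RT Dose stores 32-bit
  scaled integers, so round-trips are exact to one scaling quantum.
- Per-entry seeds come from SHA-256 hashes truncated below 2³¹.

## Known limitations

- **GTV mean at coarse DVS.** Re-voxelising a sub-cc GTV on a 0.2 cm grid
  swaps boundary voxels across a finite dose gradient and produces a
  systematic ~−0.7% mean-dose offset versus the fine-grid truth (the
  partial-volume underestimate seen in real DVS comparisons). It is stable
  across SU — the noise itself leaves the mean unbiased to <0.01% on the
  fine grid.
- **Gradient index.** The cohort's spherical symmetry makes the
  second-order (noise-variance) inflation of isodose volumes coherent
  across plans, so GI deviations drift slightly upward with SU here,
  whereas heterogeneous clinical geometries average this into no visible
  trend. GI deviations stay small relative to the index (GI ~2.5–8).
- **Cord/PRV at coarse DVS.** The cord sits in a steep trough, so 0.2 cm
  re-voxelisation mixes trough-wall doses into the cord mask and its
  near-maximum carries a few-percent positive systematic with wide IQR —
  directionally the OAR behaviour expected in a low-dose, high-gradient
  region, but magnitudes depend strongly on the synthetic trough shape.
- **Pooled size comparisons.** Comparing coverage IQRs of sub-10 cc versus
  larger PTVs across sites confounds the voxel-count effect with
  between-site systematic offsets (D98 vs D90 normalisation); within a
  site, smaller targets are cleanly noisier.
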