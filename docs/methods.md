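# Methods

## Two-material decomposition

Each voxel of the paired 80 kV / Sn150 kV acquisition is modelled as a
shared virtual-non-contrast value plus an iodine term with energy-specific
sensitivity: `HU_e = vnc + s_e · c`. The 2×2 system is inverted exactly per
voxel: `c = (HU_low − HU_high)/(s_low − s_high)`, `vnc = HU_low − s_low·c`.
The vendor decomposition behind the original workflow is proprietary; this
image-space two-material model is the standard open formulation, and it is
exactly invertible, which is what the pipeline's contracts need. Default
sensitivities are `s_low = 48`, `s_high = 15` HU/(mg/mL) — representative
of iodine at 80 kV vs a tin-filtered 150 kV spectrum — and are overridable;
all synthetic validation uses the same matrix for the forward and inverse
direction, so results do not depend on the particular values. Noise can
drive `c` negative, so the iodine map is clipped at zero by default
(concentrations are physical and the vital threshold assumes a
non-negative map); the VNC image keeps the unclipped algebraic solution.
The mixed-energy image is the linear blend `0.6·low + 0.4·high`.

Aortic iodine, the NIC normalizer, is the plain mean over the aortic ROI.
Whether the original software used mean or median is not documented; the
aorta is uniformly enhancing, so the choice is immaterial there, and the
mean is used uniformly throughout the package.

## Segmentation

The tumor segmenter reproduces a one-gesture semiautomatic workflow whose
original algorithm is undocumented, so a transparent one is used: seed
statistics (mean, SD) in a 3-mm sphere at the midpoint of the user-drawn
maximal-diameter line; connected-threshold growth within `mean ± 2.5·SD`,
restricted to a bounding sphere of 1.5× the line length; one-voxel binary
closing; keep the component containing the midpoint. A zero-variance seed
(uniform noiseless interior) admits exact intensity matches only. If the
grown region reaches the bounding-sphere boundary the result is flagged
`low_contrast` — growth was stopped by the geometric constraint, not by an
intensity edge. All parameters live in `SegmentationParams`. Liver
segmentation for phantoms is a HU band (0–250 by default) plus largest
connected component and hole filling; externally supplied liver masks are
accepted verbatim, which is the expected path for real data.

Mask morphometrics: volume is the exact voxel count times voxel volume;
the maximal diameter is the 3-D Feret diameter of surface-voxel centers
(largest pairwise distance over the convex hull of the surface points).
Whether the original measure was in-plane or 3-D is unstated; 3-D is used
and recorded as such.

## Layer peeling and the distance convention

Layers are half-open Euclidean distance bands, `(k−1)·t < d ≤ k·t`, from
the tumor margin (t = 2 mm default, 4 mm variant), computed with
anisotropic voxel spacing. Bands built from one distance field are
disjoint and exhaustive by construction, which gives the exact set-algebra
invariants (4-mm outer layer 1 is exactly the union of the two 2-mm outer
layers; tumor = VOI_I1 ∪ inner 1).

Measuring distances to nearest voxel *centers* (the naive EDT) biases band
edges by a sizeable fraction of a voxel: on a rasterized 10-mm sphere at
0.5-mm voxels the first outer shell volume comes out 8.6% below the
analytic value, and treating the mask as a union of voxel *cubes*
overshoots by ~6%. The margin is therefore localized as the 0.5-level
isosurface of the trilinearly interpolated mask indicator — an unbiased
surface estimate — implemented by supersampling the mask 2× per axis,
running an exact EDT on the fine grid, and sampling distances back at the
original voxel centers. With this convention all four 2-mm shells of the
10-mm sphere fall within ~2.2% of the analytic volumes, and band volumes
are stable under sub-voxel shifts of the sphere against the grid. The
supersampling factor is configurable (`LayerConfig.supersample`, default
2; 1 recovers the naive EDT).

Outer layers are clipped to liver ∖ exclusions (large vessels,
extrahepatic tissue); inner layers are never clipped. Distance is measured
from the tumor surface irrespective of exclusions, then clipped — bands do
not flow "around" excluded vessels. Empty regions (e.g. VOI_I2 of a tumor
with radius < 2t, or an outer band fully excluded) are recorded by name
and propagate as missing values, never as zeros.

## Quantification

Per region: `mean_hu` (mixed image), `total_ic` (mean iodine over all
region voxels), `vital_ic` (mean iodine over voxels with
`c > vital_threshold`, zero if none), `nic = vital_ic / aorta_ic`, and
`hu_ratio` = region mean HU over normal-parenchyma mean HU (orientation:
ratio > 1 for hyper-enhancing regions). "Iodine per unit volume in the
entire ROI" is interpreted as mean concentration (mg/mL); the total mass
(mg) is additionally reported for transparency. The enhancement criterion
behind "vital" was never published; `vital_threshold` defaults to
0.5 mg/mL and is configurable, and every exact NIC check in the test suite
uses uniform regions so the threshold is immaterial to those values. NIC
normalization uses vital iodine for layers as well as whole tumors,
applied uniformly. Normal parenchyma is liver ∖ (tumor ∪ outer layers ∪
exclusions) and must be non-empty. Feature rows are named
`{metric}_{region}_{thickness}mm` (e.g. `nic_outer1_2mm`).

## Cohort statistics

- **Mann-Whitney**: exact enumeration when `n_a·n_b ≤ 400` without ties,
  else the tie-corrected normal approximation; fully tied samples return
  p = 1.
- **Chi-square**: Pearson without continuity correction by default (this
  reproduces the p-values implied by the published 2×2 counts); a
  corrected variant is available via an argument.
- **ROC**: AUC is the tie-half-credit U-statistic (identical to
  trapezoidal integration — property-tested); 95% CI and paired AUC
  comparison by DeLong (the de-facto standard for correlated ROC curves;
  the original report names no method). Cutoffs maximize Youden's J, ties
  broken toward higher specificity, then toward the higher threshold; a
  case is called positive when `score ≥ cutoff`.
- **Odds ratios**: cross-product with Woolf CI; Haldane-Anscombe +0.5 on
  any zero cell; a double-zero cross pattern is undefined.
- **Logistic regression**: maximum likelihood (Newton, BFGS fallback under
  separation), Wald intervals; continuous predictors dichotomized at
  supplied cutoffs before fitting; among predictors sharing the `nic_`
  prefix only the highest-AUC one is admitted (the layer NICs are nested
  measures of one signal). Separation is reported via `converged=False`
  plus a warning, never an exception.
- **Reliability**: ICC is the two-way, absolute-agreement,
  single-measurement form (McGraw–Wong A-1; the specific ICC form was not
  published, so it is fixed here and stated); Cohen's κ for categorical
  ratings. Both are banded <0.4 / 0.4–0.6 / 0.6–0.8 / >0.8 as poor /
  moderate / good / excellent.
- **Report**: per-feature group summaries with p-values, per-feature ROC,
  univariate screen at p < 0.10, multivariate logistic on the screened
  set. Missing cells are dropped pairwise per feature; all-missing
  features are excluded with a log entry. No multiple-testing correction
  is applied (matching the original analysis); p-values are raw.

## Synthetic data: what it does and does not emulate

The phantom is a geometric scene (ellipsoidal liver, spherical or
spherical-harmonic-lobulated tumor strictly inside it, cylindrical aorta)
with piecewise-constant baselines (liver 55 HU, tumor 45 HU, aortic blood
40 HU, air background) and iodine (liver 1.0, tumor 2.5, aorta
10.0 mg/mL). MVI-positive cases add +0.5 mg/mL in the first 2 mm outside
the margin. HU noise is additive Gaussian (default SD 5 HU), independent
between channels and voxels. This validates the *pipeline* — forward/
inverse consistency, band geometry, segmentation behaviour, end-to-end
feature extraction — but deliberately omits beam hardening, scatter,
correlated reconstruction noise, respiratory motion, contrast kinetics and
anatomical texture, so passing phantom tests says nothing about clinical
discrimination performance.

The cohort generator draws each NIC feature independently per patient from
a normal truncated at zero with the published group mean/SD (defaults: the
seven reported 2-mm regions at n = 22/14). At the reported parameters
(mean/SD ≥ 2.3) the truncation shifts the mean by < 0.001, verified in the
tests. No inter-feature correlation structure was published; an optional
shared per-patient random effect can induce one, and is off by default.
The simulated expected AUC for outer layer 1 under this model is the
binormal value Φ(0.03/√(2·0.03²)) ≈ 0.760 (slightly higher after
truncation), which the replicate simulations reproduce.

## Problem sizes and numerics

Default phantom grids are 72×72×56 voxels at 1 mm (test phantoms) and the
geometry oracle uses a 10-mm sphere at 0.5-mm isotropic voxels; phantom
cohorts in the tests use 20 cases per group. These sizes keep every check
desk-scale while leaving voxelization error well inside the stated
tolerances. All generators take explicit seeds; identical inputs and
configuration give identical outputs everywhere in the pipeline (noise is
drawn from a seeded generator, segmentation and peeling are
deterministic). Degenerate inputs fail loudly with typed exceptions: empty
tumor masks, empty aortic ROIs, non-positive aortic iodine, singular
calibration, tumor-filling liver (no parenchyma), zero-variance
reliability data.

## Known limitations

- The two-material model shares one VNC value across energies; vendor
  mixed images may blend nonlinearly.
- Region growing assumes a roughly unimodal tumor intensity; necrotic or
  strongly heterogeneous lesions would need manual edits (supported as
  add/remove masks).
- Distances are Euclidean, not geodesic within the liver; bands continue
  across excluded vessels before clipping.
- The published univariate odds ratio for dichotomized outer-layer-1 NIC
  (6.42) is inconsistent with the counts implied by the published
  sensitivity/specificity at the same cutoff (which give 7.86); the
  package reproduces only count-determined quantities and does not target
  that value.
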