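# Methods

## Scope and model

`cmrqc` quantifies three stack-level quality problems of short-axis (SA)
cine cardiac MR at end-diastole: incomplete heart coverage, breath-hold
inter-slice misalignment, and low cardiac image contrast. It deliberately
does **not** attempt motion *correction*, out-of-plane motion estimation, or
detection of transient within-cycle artefacts; the pipeline scores the
overall appearance of a stack, and scans it cannot score reliably are
excluded by sanity gates rather than guessed at.

All geometry lives in world millimetres (NIfTI RAS+, voxel-centre
convention, 0-based indices). The LV long axis is the segment from the apex
landmark to the mitral-valve (MV) landmark, oriented apex → MV, so apical
structures sit at low axis coordinates; every module shares this convention.

### Landmark fusion

Each long-axis (LA) view contributes one (MV, apex) candidate pair. The
largest subset of views whose same-landmark candidates all lie within
`max_pairwise_dist` (default 20 mm ≈ 11 in-plane voxels) of each other is
retained — ties broken by total pairwise distance, then view order — and the
fused landmark is the component-wise median over retained views (the
midpoint when two survive). The sanity check fails when no pair of views
agrees; a single available view is trusted as-is. Median fusion is this
package's choice: it tolerates one grossly wrong view without averaging its
error in. How the upstream learned detector combines views is not public,
so this is a design decision, not a reimplementation.

### Coverage

Stack extent is measured at slice grid **centres**, not slab edges: an
exactly-spanning stack then scores exactly 100%, and the formula

    coverage = 100 · (L − basal_gap − apical_gap + basal_overhang + apical_overhang) / L

degenerates to `100 · (max s − min s) / L` in every regime. Gaps and
overhangs are always reported when non-zero, not only for sub-optimal
stacks. Whether the original pipeline used centres or edges is not
recoverable; the edge convention would add one slice thickness to every
span and is deliberately not the default.

### Misalignment

The reference LV position is a 3-D total-least-squares line through the
blood-pool centroids of the LA views (one centroid per pixel line along the
cavity's long dimension, pooled over views, fitted via SVD), intersected
with each SA slice plane. The observed position is the sub-voxel centre of
mass of the slice's blood-pool mask. The per-slice misalignment is the
Euclidean norm of their in-plane difference; centroid matching is the
simplest translation estimator consistent with "the in-plane translation
required for approximate realignment". Only slices strictly between the
landmarks are assessed, ordered apex → base; the regional averages take the
first 2 (apical), last 2 (basal) and remaining (mid) slices, so the overall
average equals the count-weighted mean of the regional ones by construction.

A slice whose centre lies within half an in-plane pixel (0.9 mm at default
spacing) of a landmark plane is treated as a boundary slice and excluded
from assessment: any cross-section there is below the sampling resolution,
and a blood-pool mask on such a slice is empty for geometric rather than
segmentation reasons.

### Contrast

Per assessed slice, `100 · (mean blood-pool − mean myocardium) / (max − min)`
of that slice's image. The dynamic range is per-slice by default ("the
image" is ambiguous; a per-stack range is available via
`dynamic_range="stack"`). Slices with zero dynamic range or an empty
myocardium mask are excluded with a recorded reason; if every assessed slice
is excluded the check is sanity-failed. Probabilistic masks are binarized
(argmax, ties → background) before intensity averaging.

### Classification thresholds

Defaults: coverage < 100% sub-optimal and < 90% severe (strict comparisons,
so exactly 100% counts as full); average misalignment ≥ 3.4 mm motion-
corrupt (boundary included — the threshold that best separated visually
motion-corrupted stacks in the validation of this QC approach, at 1.8 mm
in-plane resolution); average contrast < 30% low, < 20% very low. A
sanity-failed check is *excluded*, never flagged, and exclusion counts are
carried through the cohort summary so that `n_analysed + n_excluded =
n_complete` holds per check.

## Segmentation and landmark stand-in

The production pipeline obtains segmentations and landmarks from a learned
model; training such a model is out of scope here and the package instead
provides a deterministic classical extractor to keep the pipeline runnable
end-to-end: blood pool = largest connected component above the upper
three-class Otsu threshold, myocardium = the intermediate-intensity band
intersected with a morphological ring around the blood pool (Otsu thresholds
are moved from bin centres to upper bin edges to avoid quantization leaking
threshold-bin intensities into the wrong class). LA landmarks come from the
cavity mask's principal axis: the basal end is the wider end, the MV
candidate is the centroid of the basal-most pixel line (the open edge), the
apex candidate the centroid of the line farthest from it. On noise-free
phantoms this extractor reproduces the ground-truth masks essentially
exactly and places landmarks within half a voxel; it is a stand-in for
testing the downstream metrics, not a segmentation method for clinical
images. The ground-truth injection path (`source="ground_truth"`) bypasses
it entirely.

Reliability heuristics operationalise "segmentation unreliable": empty
blood-pool mask on an assessed slice; blood-pool area changing by more than
300% between adjacent assessed slices (only when the smaller area is at
least `min_area_mm2 = 150` — near the apex the true cross-section shrinks
to a point and large relative changes are anatomy, not failure); myocardium
failing to form one connected ring enclosing the cavity on more than half
the assessed slices; fewer than 6 assessed slices. All thresholds are
keyword-configurable.

## The synthetic data layer

### Phantom

The LV is a half-ellipsoid shell: blood pool and epicardium are ellipsoids
sharing the apical tip (long semi-axis `lv_long_axis_length`, default
90 mm), with transverse radii `cavity_radius` (20 mm) and `cavity_radius +
myo_thickness` (30 mm). The MV landmark is the centre of the basal opening,
the apex landmark the shell tip; because both surfaces share the tip, every
plane strictly between the landmarks has a non-empty circular blood-pool
cross-section and the myocardial wall tapers toward the apex. Acquisition
geometry defaults follow the targeted population-imaging protocol: 1.8 mm
in-plane pitch, 8 mm slices with 2 mm gap (10 mm centre spacing), ~10 SA
slices, three LA planes containing the axis at azimuths 0°/60°/120° (a
geometric stand-in for the 2-/3-/4-chamber orientations — the labels are
cosmetic). The default 96×96 image size keeps tests fast; it is
configurable up to scanner matrix sizes.

Defects are injected analytically. Truncations move the stack's first slice
centre to `apical_truncation` and drop slices beyond
`L − basal_truncation` (negative values create overhang); truth coverage
and gaps are computed from the *realized* slice centres. Per-slice in-plane
shifts displace the heart content of each slice; intensities are constant
per tissue (defaults blood 200, myocardium 80, background 0 — 60% contrast)
with optional additive Gaussian noise, the only stochastic element.

Two sampling choices make closed-form truth recoverable to numerical
precision rather than to voxel order: voxelization samples the implicit
model at pixel centres, and each SA slice's pixel grid is translated along
with its displaced content so the grid stays 180°-symmetric about the
displaced cavity centre — pixel-centre sampling of a centrally symmetric
region on such a grid preserves the centroid exactly. Likewise LA grids are
symmetric about the long axis, so per-line cavity centroids fall exactly on
it. A binary mask on a fixed regular grid has a piecewise-constant
centroid, so exact recovery of continuous shifts is impossible without
this construction. The consequence is that a shifted phantom stack is not
grid-regular; the NIfTI writer therefore emits the nominal affine plus a
JSON geometry sidecar with exact per-slice origins and directions, which
the reader restores.

What the phantom does *not* emulate: MR physics (b-SSFP banding, bias
fields, flow), papillary muscles and trabeculation, out-of-plane
respiratory motion, and non-elliptical ventricle shapes. Passing the
recovery tests therefore demonstrates correctness of the geometry and
metric computations, not robustness to realistic image content — that is
what the learned extractor being replaced would provide.

### Cohort generator

Per-subject covariates (weight, BMI, BSA via Mosteller, age, blood
pressure, lifestyle categories, self-reported condition codes, site,
acquisition date) are drawn from plausible population-scale distributions.
Average misalignment is log-normal — positive and right-skewed, matching
the published population summary (median 2.29 mm, IQR 1.17 mm; the
log-normal form itself is this package's choice, the source reports no
distributional family) — and is tied to weight through a Gaussian copula.
For a Gaussian copula Kendall's τ = (2/π)·arcsin ρ exactly, and τ is
invariant under the monotone marginal transforms used, so the generator
hits a requested population τ-b by setting ρ = sin(πτ/2) in closed form
(calibration point: τ = 0.21, the published weight–misalignment
correlation). Contrast and coverage are Gaussian (contrast median 39%,
IQR 6%), with an optional between-site location shift on coverage.
Body-surface area uses height inferred from BMI:
`BSA = sqrt(100·sqrt(w/bmi) · w / 3600)` m².

## Statistics

* **Anderson–Darling** (composite normality, mean and variance estimated):
  the statistic is the textbook sum; the p-value applies the small-sample
  correction A* = A²(1 + 0.75/n + 2.25/n²) and the standard case-3 tail
  approximation. scipy's implementation provides only critical values and
  serves as the independent cross-check of the statistic in the tests.
* **Rank-sum with CI**: two-sided Mann–Whitney p (exact by full null
  enumeration for tie-free samples with n₁, n₂ ≤ 10, tie-corrected normal
  otherwise, via scipy). The "95% CI of the difference between medians" is
  realized as the Hodges–Lehmann / Mann–Whitney-inversion interval over the
  n₁·n₂ pairwise differences — the standard rank-sum-associated interval;
  the source names no other construction. Critical orders come from the
  exact null distribution (dynamic programming) for n₁·n₂ ≤ 2500 and from
  the continuity-corrected normal approximation beyond.
* **Kendall τ-b** with tie correction and **OLS** via scipy.
* **Multiple testing**: only the motion family is corrected. Its default
  plan holds exactly 19 tests (11 covariate tests + 8 condition-vs-healthy
  contrasts), giving p_corr = 0.05/19 ≈ 0.0026; the regional and
  weight-quintile contrasts are run as descriptive comparisons outside the
  corrected family, and the small coverage (4-test) and contrast (2-test)
  families are uncorrected. Missing covariates are deleted pairwise per
  test; a test with an empty group is recorded as skipped, not failed.
* **Quintile groups** use strict inequalities around the 20th/80th
  percentiles (linear interpolation between order statistics); **IQR** is
  the 75th minus 25th percentile under the same percentile rule. The
  never-vs-current smoking contrast excludes former smokers.
* Acquisition-period contrasts compare the Apr 2014–Sep 2015 window against
  Aug 2017–Feb 2018 (configurable date windows).

## Numerical conventions and degenerate inputs

Display percentages round half-up to one decimal; full precision is kept
internally and JSON reports serialise deterministically (sorted keys, fixed
float formatting). End-diastole is temporal frame 0 of a cine file
(configurable on read). Degenerate cases fail loudly where a result would
be meaningless (no landmark views, single-slice stacks for coverage,
all-tied samples for τ-b, zero-variance samples for Anderson–Darling) and
fail *soft* where exclusion is the correct outcome (missing subject images,
empty test groups, zero-dynamic-range slices, landmark sanity failures).

## Problem sizes in the shipped tests

The acceptance suite uses 200 truth-mask and 50 extracted-mask phantoms at
96×96 resolution, 2000-replicate type-I-error simulations (n = 500 for
Anderson–Darling, 50 + 50 for the rank-sum), 1000 shifted-normal pairs for
CI coverage, and a 10,000-subject cohort for the τ-b calibration check —
sizes at which the Monte-Carlo envelopes quoted in the tests are
comfortably stable on a single CPU.

## Known limitations

The extractor is intensity-threshold-based and will not survive clinical
image content; the phantom's exact-recovery guarantees quantify the metric
implementations, not end-to-end accuracy on real scans. Misalignment is
in-plane only, as a proxy for full breath-hold motion. The coverage
centre-vs-edge convention and the reference pipeline's "unreliable
segmentation" criteria are unrecoverable from public sources; both are
explicit configuration points here.
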