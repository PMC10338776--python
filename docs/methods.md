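# Methods

This note documents the models, numerical choices and known limitations
of centiz. It is written for a maintainer or reviewer who wants to know
*why* the pipeline is built the way it is, and what the synthetic
validation does and does not demonstrate.

## Geometry and resampling

Volumes carry a voxel-to-world affine (mm); index `i` addresses the
center of voxel `i`. All transforms act on world coordinates and are
composed into a single 4×4 matrix before resampling, so a subject's PET
is interpolated exactly once regardless of how many pipeline stages
contributed transforms (single-resampling rule; repeated interpolation
would accumulate blur and bias VOI means). Resampling uses the
pull-back convention — the transform maps target world coordinates into
source world coordinates — with trilinear interpolation for images,
nearest-neighbour for masks, and out-of-field voxels set to 0, matching
the implicit-zero convention of the surrounding neuroimaging ecosystem.
On NIfTI input the sform is preferred over the qform (falling back to a
voxel-size-scaled identity), NaNs are replaced by 0 with a logged
count, and multi-frame files are rejected.

## Registration

Both spatial stages maximize normalized mutual information,
NMI = (H(A)+H(B))/H(A,B), over a joint histogram with 64 equal-width
bins spanning the 1st–99th intensity percentiles and partial-volume
(bilinear) bin weighting, which makes the metric smooth in the
transform parameters. The metric is always evaluated over the full
(strided) fixed grid with out-of-field samples entered as 0: evaluating
only over the overlap region lets the optimizer shrink the overlap to
voxels that score well, which manifests as a percent-level scale bias.

The optimizer is a derivative-free Powell search over a three-level
image pyramid (downsample factors 4/2/1 with 32/48/64 bins and sampling
strides 1/2/3; Gaussian pre-smoothing at σ = factor/2 voxels). These
defaults recover rigid misalignments of a few mm/degrees to well under
0.1 mm on noiseless phantoms and keep a full subject registration
around ten seconds on one CPU at 64³; they are deliberate
accuracy/runtime choices, adjustable via `RegistrationOptions`.

* **Reorientation** is implemented as automatic center-of-mass
  initialization of the translation, not manual AC–PC alignment.
* **Rigid coregistration** (PET → structural): 6 parameters, intrinsic
  XYZ Euler angles (radians) about the fixed image's center of mass.
* **Template normalization** (structural → template): tissue-prior
  "unified segmentation" is deliberately **not** reimplemented. The
  stand-in is a 12-parameter affine (translations, rotations, scales,
  shears) seeded by the rigid stage. A smooth nonlinear refinement flag
  exists but is off by default and currently a documented no-op: the
  synthetic test surface is generated by rigid/affine deformation of
  the template, for which the affine family is exact. **Real-data
  parity with tissue-prior normalization is therefore not claimed** —
  this is the main known limitation for clinical images with
  genuinely nonlinear anatomy.

Because NMI depends only on the joint intensity distribution, the same
code registers MRI-like and CT-like structural images (inverted
soft-tissue contrast, bright skull rim) without modality-specific
handling; a phantom test exercises the CT arm.

## SUVR and Centiloid

SUVR = mean(CTX) / mean(WhlCbl), unweighted means over binary VOI
masks; probabilistic masks are thresholded at > 0.5 (logged).
Quantification is always performed in template space where the standard
VOIs live; masks are resampled nearest-neighbour if grids differ, and a
VOI coverage below 0.9 (fraction of mask voxels with finite in-field
data) is an error rather than a silent bias. The florbetapir conversion
CL = 175.2·SUVR − 182.2 is exact and exactly invertible.
`validate_calibration` regresses computed on reference CL (reference on
the x-axis, R² = squared Pearson r); slope/intercept bounds are
inclusive, the R² bound strict, per the usual reading of the
calibration criteria.

## Normative database and Z maps

Controls (template space) are smoothed — separable Gaussian,
σ_axis = FWHM/(√(8 ln 2)·voxel_axis), zero-padded, default 8-mm FWHM —
then divided by their reference-VOI mean, and reduced to voxel-wise
mean and sample SD (n−1). The white-matter exclusion the analysis
requires is not specified anatomically anywhere authoritative, so it is
implemented as a data-driven proxy: the analysis mask removes in-brain
voxels whose database mean exceeds the 0.85 quantile of in-brain mean
values (configurable, or replaceable by an explicit mask). Z is
computed inside the analysis mask only, with the SD floored at
max(ε, 0.05 × median in-mask SD) to prevent Z explosions at
near-constant voxels; sub-half-voxel FWHM requests are treated as
no-ops with a warning.

"Mean positive Z" is the mean over *strictly positive* voxels of the
target VOI (0 when none are positive) — the alternative reading
(positive part of the VOI mean) was rejected as inconsistent with the
phrase "positive Z-score". Cluster reporting uses 18-connectivity by
default (6/26 available) with a configurable size threshold.

One statistical caveat the phantoms made explicit: with a small control
cohort whose between-subject SUVR spread dominates the voxel SD, a
*single* null subject's in-mask mean Z equals its cohort deviation
(order ±1), not ≈0. The null property that is actually stable — and
what the validation measures — is the *average* over members of the
leave-one-out mean Z, which is near zero by symmetry.

## Agreement statistics and permutation FWE

Pearson/Spearman use the standard product-moment and mean-rank
formulations (scipy implementations, cross-checked in the tests against
closed-form hand oracles). Bland–Altman reports both conventional
limits of agreement (bias ± 1.96·SD of differences) **and** the t-based
95% CI of the bias: published "95% limits of agreement" ranges in this
literature are sometimes numerically a CI of the mean difference, so
both are emitted rather than guessing, with the difference orientation
an explicit parameter.

The voxel-wise paired t-test controls family-wise error by sign-flip
maxT permutation instead of random-field theory: under exchangeability
of paired-difference signs it is exact, needs no smoothness estimation,
and is cheap at these sizes. All 2ⁿ sign patterns are enumerated when
2ⁿ ≤ n_perm (e.g. n = 8 pairs → 256 patterns), otherwise n_perm random
patterns including the identity. The critical value is the ⌈(1−α)P⌉-th
order statistic of max|t|; supra-critical voxels (strict inequality, so
a degenerate all-zero distribution yields no detections) are clustered
at 18-connectivity and filtered by the extent threshold (default 300
voxels), reported separately for each direction. Two-sided throughout.

## Synthetic phantoms

The generator emulates the *structure* of an amyloid-PET study, not its
physics. Geometry is a nested-ellipsoid brain (64³ @ 2 mm by default):
cortical shell, central white-matter core, and an inferior cerebellum
blob placed fully inside the brain. PET uptake is piecewise constant
with the reference region at 1, cortex at the requested true SUVR, and
white matter at 1.55 — the florbetapir-negative pattern (WM > cortex),
which both gives the white-matter exclusion something real to remove
and lets amyloid-positive subjects raise cortex toward and above WM.
The quantification VOIs are eroded inward from the painted regions
(cortex shell at 0.80–0.92 of the brain ellipsoid; cerebellum VOI at
0.60 of the painted blob) so that the one-to-two-voxel interpolation
blur of misalignment + resampling cannot reach them: noiseless,
untransformed phantoms recover their true SUVR exactly, and the
full pipeline recovers CL to a fraction of a CL unit. Structural
fields (MRI-like: bright WM; CT-like: compressed soft tissue, bright
skull rim) are smoothed with a 1-voxel Gaussian because real anatomy
has smooth transitions — and because registering a sharp template to a
trilinearly blurred copy of itself biases NMI by a percent-level scale.

Control cohorts draw true SUVR from Normal(0.986, 0.052) truncated
below at 0.8 (a young amyloid-negative florbetapir cohort); calibration
sets space true CL evenly over [−20, 120] with per-subject random rigid
head pose and PET-vs-structural misalignment, both bounded by 5 mm /
5° (translations uniform in the ball, per-axis rotations uniform).
Noise is additive Gaussian at 2% of the reference mean by default.
Everything is deterministic given the seed.

What passing these tests shows: the geometry/transform bookkeeping,
the metric, the optimizer, the VOI statistics, the database algebra and
the inference machinery are correct under a generative model where the
true deformation lies in the search family. What it does not show:
performance on real scanners' point-spread functions, scatter,
nonlinear anatomy, lesions, or atypical positioning.

## Problem sizes used in the validation

The standard self-validation (tests and `scripts/acceptance.py`) uses
20 calibration phantoms at 64³, a 20-control database, 20 null runs of
8 pairs for FWE calibration (24³ fields), a ~500-voxel injected blob at
32³, and 20 rigid-recovery draws at 52³ — sizes chosen so the whole
battery runs in a few minutes on a single CPU while keeping every
check's statistical margin wide.
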