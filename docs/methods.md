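# Methods

## Model

The classifier treats a 3-D template-space volume as the set of all of its
orthogonal 2-D planes.  For dims (nx, ny, nz) there are nx sagittal, ny
coronal and nz axial planes, ordered sagittal-ascending, then coronal, then
axial; this ordering is the contract shared by the slice extractor, the
per-submodule probability vector, and the interpretation stage.

Each plane has a private submodule: four blocks of 3×3 convolution
(stride 1), batch normalization, ReLU, and 2×2 max pooling (stride 2),
followed by a dense unit and sigmoid.  Default filter counts are
(32, 64, 128, 128).  The per-slice sigmoid outputs are concatenated and
fused by a single dense unit with sigmoid.  The decision rule is strict:
positive iff the final probability exceeds the threshold (default 0.5);
a probability of exactly 0.5 is negative.

Training uses binary cross-entropy on the final output only, Adam at
learning rate 1e-4, mini-batches of 4, up to 30 epochs, with validation
loss monitored each epoch and the best-epoch weights restored at the end
(ties keep the earlier epoch).  Convolutions are He-initialized, dense
layers Xavier-initialized.  A non-finite training or validation loss
aborts with a diagnostic rather than continuing.

Choices made where the recipe is open:

- **Padding** is unstated upstream; we use same-padding (pad 1), so only
  pooling reduces resolution.  This keeps the four-block stack valid for
  91-pixel planes and is the common reading of the architecture.
- **Loss supervision**: the per-slice sigmoids receive no auxiliary
  losses; gradients reach them only through the fusion head.  The fusion
  head consumes the post-sigmoid slice probabilities.
- **Pooling** uses floor division for odd extents, so each in-plane
  dimension must be at least 16 to survive four halvings; violations fail
  loudly naming the offending dimension.
- **Conv bias** is omitted: the following batch-norm shift makes it
  redundant.
- **Validation split**: stratified 80/20 with a recorded seed when no
  explicit validation set is supplied.
- No learning-rate schedule, weight decay, or augmentation.

### Implementation

The network is a hand-written numpy layer stack.  All submodules of one
axis share a slice shape, so their parameters are stacked along a leading
submodule dimension and each layer is evaluated for the whole axis with
batched BLAS matmuls (im2col convolution; the backward pass uses nine
shifted slice-accumulations instead of scatter).  Reverse-mode gradients
are derived per layer and verified in the test suite against central
finite differences in float64 at step 1e-6 (relative tolerance 1e-4).
Arithmetic is float32.  Inference runs batch norm on running statistics
and is exactly deterministic for fixed weights.

## Preprocessing

`normalize_by_reference` divides every voxel by the mean over a reference
mask (default "pons"), making the reference mean exactly 1; the operation
is idempotent and invariant to global rescaling.  No further per-slice
standardization and no background masking are applied.  Voxel indices are
0-based; millimetre coordinates exist only through the NIfTI affine
(x = sagittal index, y = coronal, z = axial).

## Amyloid positivity rules

SUVR(ROI) = mean(ROI voxels) / mean(reference voxels), reference
"cerebellum" by default (whole region as named in the atlas; whether a
grey-matter-only cerebellum is wanted is an atlas configuration question,
not code).  Rules (comparison strict in every case):

| tracer       | mode        | threshold |
|--------------|-------------|-----------|
| florbetapir  | global      | 1.11      |
| PiB          | any of ROIs | 1.4       |
| florbetaben  | any of ROIs | 1.478     |

The global (composite) SUVR is the voxel mean over the *union* of the
target ROIs, not the mean of per-ROI SUVRs.  Target-ROI name lists are
configuration: real parcellations differ between datasets, and toy atlases
use any four regions.

## Interpretation

Subjects are grouped by the model's predicted class (not ground truth).
Per submodule, a two-sample t-test (Welch by default; pooled available)
compares probabilities between groups; each predicted class needs at least
two members.  Slices with p < α (default 0.05, two-tailed) form per-axis
sets whose Cartesian product is the point cloud; its cardinality is the
product of the set sizes.  Points are tallied per atlas region (background
excluded) and regions holding strictly more than `min_points` survive,
sorted by count.  A connected-component alternative on the point cloud
itself is provided (`mode="connected"`).  No multiple-testing correction
is applied across the per-slice tests.  Zero-variance submodules are
excluded rather than declared significant.

The construction deliberately over-generates: only slice marginals are
tested, so most points are unrelated to any joint signal, and the
`min_points` filter is the only pruning step.  On toy volumes the default
of 50 still discriminates well because seeded regions reach full coverage,
but the parameter should be scaled with volume size in other designs.

## Voxel-wise analysis

Per-voxel two-sample t (pooled variance by default, matching the classical
two-sample imaging design; Welch optional — the asymmetry with the
interpretation default is deliberate) over an analysis mask (default: the
atlas's labelled voxels).  Voxels with zero variance in either group are
removed from the mask and counted.  Thresholding: uncorrected p,
Bonferroni, or permutation max-T familywise correction (label
permutations, corrected p = fraction of permutation maxima of |t| at or
above the observed |t|).  Parametric random-field FWE is not implemented.
Suprathreshold voxels are split by t sign; connected components
(18-connectivity default, 6/26 available) of size ≤ k are discarded
(survival strictly > k, default 50).

## Evaluation

Accuracy, sensitivity, specificity, F1 = 2·TP/(2·TP+FP+FN), and AUC with
midrank tie handling.  The repeated protocol draws R stratified 80/20
splits (default 50), fits a fresh model per split, and reports per-metric
mean with a 95 % CI — normal approximation mean ± 1.96·SD/√R by default,
percentile bootstrap optional (the presentation of a mean with 95 % CI
leaves the CI construction open; both modes are provided).  The single
best repetition is selected by internal-validation AUC and, when an
external set is supplied, re-evaluated externally.  Subgroup reports
(CU / MCI / dementia) compute the same metrics on each diagnosis stratum;
strata lacking a class report the defined metrics with AUC as NaN.

## Synthetic data

The generator reproduces the statistical structure the analyses assume,
not anatomy or PET physics (no scanner PSF, attenuation, or
reconstruction):

- **Toy atlas**: cubic boxes (edge 4–8 voxels, ≥ 60 voxels each) on a
  regular grid, a seeded random subset labelled as n cortical regions plus
  dedicated "pons" and "cerebellum" reference regions.  Capacity failures
  name the constraint.
- **FDG-like cohort**: per-region baseline constants drawn once from
  [0.8, 1.2); a subject-level lognormal global scale (log-SD 0.15) — the
  nuisance pons normalization removes; positives' hypo regions scaled by
  (1 − effect) and hyper regions by (1 + effect); additive Gaussian voxel
  noise (SD relative to the unit baseline); separable Gaussian smoothing
  with FWHM = 2.355 σ.  Defaults: effect 0.15, noise 0.05, smoothing
  FWHM 2 voxels — values chosen once as a clearly detectable desk-scale
  regime (the magnitude of real group differences in regional metabolism
  is not specified by the source analyses, so these are stated
  conditions, not estimates).
- **Prevalence**: exact-count mode by default (e.g. exactly 50 of 100
  positives), Bernoulli mode optional; a class emptied in exact-count mode
  is an error.  Diagnosis subgroups are assigned independently of the
  amyloid label (defaults 40/40/20 % CU/MCI/dementia).
- **Amyloid-tracer-like cohort**: target-ROI-to-cerebellum ratios drawn
  above threshold + margin for positives and below threshold − margin for
  negatives; with margin > 0 the rule recovers the labels exactly.
  Smoothing is disabled here because it couples ROI means to the zero
  background and would distort the constructed ratios.

What passing tests on these cohorts do **not** show: robustness to
registration error, scanner and site effects, anatomical variability,
partial-volume effects, or realistic spatial covariance — real FDG data
are far harder, and the published real-data performance (internal AUC
0.811, external 0.798, best-model 0.860) cannot be reproduced here because
those datasets are access-restricted.

## Problem sizes used in the checks

The automated checks run a scaled-down study: volumes 24×28×24 (76
submodules), 200 subjects, filter counts (8, 16, 32, 32), 10 epochs,
interpretation at α = 0.05 with the default 50-point ROI filter, and
voxel-wise thresholding at uncorrected p < 0.001 with k = 50.  At this
scale the seeded regions are recovered by both the interpretation and the
voxel-wise routes, and held-out AUC saturates; these sizes are the
package's chosen desk-scale study conditions.

## Known limitations

- The Cartesian interpretation is a coarse surrogate for spatial
  attribution; it cannot localize within a slice and over-plots by design.
- Permutation FWE is exchangeability-based and assumes no nuisance
  covariates; no GLM covariate adjustment is provided.
- Batch norm with mini-batches of 4 makes training curves noisy; training
  is reproducible for a fixed seed on one machine but not guaranteed
  bit-identical across BLAS builds.
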