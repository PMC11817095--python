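# Methods

`dentage` estimates chronological age (in years) of pediatric subjects
from two modalities: a grayscale panoramic radiograph (OPG) and a vector
of numeric patient-record fields. The pipeline has four stages — dual CNN
feature extraction, early fusion, a genetic-algorithm-optimized random
forest (MG-RF), and a regression metric suite — plus a synthetic cohort
simulator that makes the whole system testable without clinical data.

## The model

### Feature extractors

Each modality gets its own small convolutional network ending in a linear
feature layer:

- **Image path (2-D CNN).** Four blocks of 3×3 convolutions ("same"
  padding, stride 1, ReLU) with 32/64/128/256 filters, each followed by
  non-overlapping 2×2 max pooling, then a 512-unit ReLU dense layer and a
  128-unit *linear* feature layer. The canonical input is (224, 224, 3);
  grayscale OPGs are replicated across the three channels.
- **Record path (1-D CNN).** Three 1-D convolutions (16 filters of width
  5, then 32 and 64 of width 3 — two stacked width-3 kernels cover the
  receptive field of one width-5 kernel with fewer parameters), a global
  max pool, a 256-unit ReLU dense layer, and a 128-unit linear feature
  layer.

Although the downstream task is regression, the extractors are trained as
*classifiers*: a temporary softmax head over equal-width age bins
(default one bin per integer year of the training age range, i.e. 9 bins
for a 6–15-year cohort) is attached above the feature layer and trained
with cross-entropy via Adam on mini-batches. At extraction time the head
is discarded and the 128-unit linear activations are the features. This
lets the feature layer organise itself around age structure without ever
seeing continuous labels, and keeps extraction a pure deterministic
forward pass.

The layers are implemented in plain numpy (`dentage.nn`): im2col
convolutions, pooling with argmax routing on the backward pass, and Adam.
The backward pass is verified against central finite differences in the
test suite. Everything is seeded, so training twice with the same
data/config/seed is bit-identical — the package's determinism guarantees
rest on this.

### Fusion

Per-patient feature vectors are concatenated (image block first, columns
prefixed `img_`/`rec_`), giving 256 fused features at the default widths.
Alignment is by explicit patient-id comparison; mismatches raise rather
than silently reindex. A width-60 image path with a width-15 record path
(an alternative convention for the same architecture family) fuses to 75;
both widths are exercised in the tests.

### MG-RF regressor

A generational genetic algorithm searches jointly over:

1. **Hyperparameter genes** — 5 integer indices into a fixed grid:
   max_depth {10, 20, …, 100, None}, max_features {'auto', 'sqrt'} (both
   decode to √d candidate features per split), min_samples_leaf
   {1, 2, 4}, min_samples_split {2, 5, 10}, n_estimators {200, …, 2000}.
2. **A tree-retention bitmask** — one bit per tree up to the largest grid
   ensemble size; bit t = 1 keeps tree t in the averaged prediction,
   0 drops ("denounces") it. A repair step guarantees at least one
   retained tree in the active window.

Fitness of a chromosome is the validation error (MSE by default, MAE
optionally) of the *masked* ensemble: the base `RandomForestRegressor`
is fitted once per decoded hyperparameter combination at its full size,
per-tree validation predictions are cached, and the mask selects the
sub-ensemble whose arithmetic mean is scored. Because fitting is
deterministic under the run seed, fitness is memoized across the whole
run and elites never pay twice.

GA settings default to: population 20, 50 generations, tournament
selection of size 3, single-point crossover at rate 0.8 applied
independently within the gene segment and within the mask segment (the
segments never mix), per-gene/per-bit mutation at rate 0.1 (gene →
uniform resample on its axis, bit → flip), and 1 elite. With elitism ≥ 1
the per-generation best fitness is non-increasing; the suite asserts
this. An optional fitness threshold stops evolution early; by default all
generations run. The mask search can be disabled
(`GAConfig(optimize_tree_mask=False)`), restricting the GA to the
hyperparameter grid.

`fit_mgrf` splits its rows internally (75/25, stratified by integer
age-year, seeded) into GA-train/GA-validation, runs the GA, then refits
the best chromosome's decoded forest on *all* of its rows with the
retention mask applied. It also reports an impurity-importance feature
ranking from a seeded reference forest. Prediction is the mean over
retained trees only, and is checked in the tests against an explicit
tree-by-tree averaging oracle to 1e-9.

### Preprocessing

- **Cleaning**: row-wise deletion of any manifest row with a missing,
  blank, or non-finite field (no imputation).
- **Images**: per-image min–max scaling to [0, 1] (invariant to positive
  affine intensity rescaling; a constant image maps to zeros with a
  warning).
- **Records**: per-column Z-score with population (n) SD, fitted on the
  training split only and reused on held-out rows. Sex enters the record
  matrix as a trailing 0/1 column. Ages (labels) are never standardised;
  every reported error is in years.

### Metrics

SD of signed residuals (predicted − actual), MAE, MSE, RMSE and R², all
with population (n) denominators and R² about the mean of the actual
values. `RegressionReport` carries a consistency flag checking the
identity RMSE² = MSE, so externally reported (MSE, RMSE) pairs can be
machine-screened before comparison — reported quadruples in this
literature are not always internally consistent.

## The synthetic cohort

The simulator (`dentage.synthetic_cohort`) emulates the demographic and
signal structure of a pediatric OPG archive:

- **Demographics.** Sex ~ Bernoulli(275/346 male:female odds); age per
  sex from a normal with SD 2.5 years truncated to 6–15. The location
  parameter is calibrated by root-finding so the *truncated* mean equals
  the target sex mean (10.94 male / 11.1 female) — truncation is
  asymmetric here, so centring the untruncated normal on the target would
  bias the cohort mean low by ~0.2 years.
- **Images.** Seven left-mandibular teeth along a simulated arch: a fixed
  elliptical crown plus a tapering root whose rendered length is the
  tooth's root-completion fraction `clamp((a − onset_t)/duration_t, 0, 1)`
  at *dental* age `a`, with per-tooth onsets spanning the age range and a
  duration of one third of it. Dental age is chronological age plus
  N(0, `dental_timing_sd`= 0.75 years): individuals of the same
  chronological age genuinely differ in developmental stage, which is the
  premise of dental age estimation, and it gives the image modality an
  irreducible error floor distinct from the record modality's. Additive
  Gaussian pixel noise (SD 4 on the 0–255 scale) is applied last. With
  noise off, total rendered tooth area is non-decreasing in
  chronological-age inputs — the monotone staging signal the image CNN is
  meant to learn.
- **Records.** Field j = slope_j·age + intercept_j + N(0, 1), with
  default slopes ramping over [0.5, 1.5] across the 15 fields so each
  carries age signal of a different strength. OLS on a 500-patient cohort
  recovers the slopes within 3 standard errors (asserted).

What the simulator does **not** model: anatomical realism, projection
geometry, restorations/artifacts, sex-specific developmental timing,
non-linear record–age relationships, and correlated record noise.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that it recovers a planted multimodal age signal; they say
nothing about accuracy on clinical radiographs.

## Study sizes and numerical choices

The package's desk-scale study configuration
(`dentage.pipeline.desk_scale_config`) is the setting used by the test
suite and by `scripts/acceptance.py`: a 600-patient cohort, 64×64 images
into a narrowed image CNN (8/16/32/32 filters, 128-unit dense, per-path
feature width kept at 128 so the fused width stays 256), 8 training
epochs with batch 32 and learning rate 1e-3, and a GA of population 20
over 10 generations on a reduced tree grid (100/200 estimators, depths
{10, 20, None}). These sizes were chosen once as a single-CPU-friendly
reduction that preserves every structural element of the full
configuration; the full printed defaults remain the class defaults.

Other numerical decisions:

- Train/test split 80/20, stratified by integer age-year with exact test
  size; strata with fewer than two members are merged before
  stratification.
- Weight initialisation is He-normal, seeded; mini-batch order is drawn
  from the same seeded generator; there is no dropout or batch
  normalisation (the architectures above are complete).
- Equal-width age bins are computed from the training rows' age range;
  held-out rows never influence bin edges.
- Ties in feature-importance ranking break by ascending feature index.
- A constant (zero-variance) standardisation column maps to zero with a
  warning rather than dividing by zero; a constant image likewise maps to
  zeros.
- The GA's "without concatenation" ablation is late fusion: the
  unweighted average of the image-only and record-only MG-RF predictions.
  The "without 2-D CNN" / "only 1-D CNN" pair (and its mirror) differ in
  pipeline wiring but evaluate the same single-modality feature set, so
  their reports coincide by construction.

## Known limitations

- The numpy CNN is CPU-bound and sized for desk-scale experiments; the
  224×224 default architecture is exercised for shape contracts, not
  trained at scale in the test suite.
- The GA refits one base forest per *distinct* hyperparameter
  combination; on very large grids with high mutation rates this is the
  dominant cost.
- `evaluate_regression` refuses zero-variance actuals (R² undefined)
  rather than returning a sentinel.
- Synthetic-to-clinical transfer is out of scope; see the simulator's
  non-modelled features above.
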