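# Methods

## Problem and pipeline

A single fixed monocular camera observes fish in a turbid tank. Apparent
pixel size confounds body size with camera-to-fish distance ("depth",
here always the horizontal camera distance in cm, not water depth), so a
detected fish's weight is estimated by a cascade of three regressions:
depth from (age, pixel length, pixel width); centimetre dimensions from
the same features plus the estimated depth; weight from everything. At
training time each stage consumes *annotated* values — measured pixel
dimensions, marker-read depth labels, tape-measured centimetre
dimensions — while at prediction time each stage consumes the upstream
stage's own estimates, exactly as deployed. Age is a user-supplied prior
(farmers know their stocking calendar); it is the only non-image input.

## Synthetic data generator

The generator emulates the data-collection protocol the method was
designed for; it is first-class, tested code, not a fixture.

* **Growth.** Cohort weight is normal, truncated at zero, with mean and
  SD interpolated linearly in age between two anchor weighings:
  166.45 ± 26.38 g at week 20 and 482.24 ± 91.64 g at week 28. Only the
  two endpoint statistics are available, so linear interpolation is the
  minimal assumption. Length follows the cube-law allometry
  L = (W/a)^(1/3) with a = 166.45/20³ ≈ 0.0208 g/cm³, placing the mean
  week-20 fish at 20 cm and the mean week-28 fish at ≈28.5 cm, inside the
  observed 20–30 cm range; width = 0.38·L gives 7.6–10.8 cm, inside the
  observed 7–12 cm. Weight, length and width are therefore exactly
  allometrically consistent per fish; all individual variation enters
  through the weight draw.
* **Camera.** Pinhole projection, focal length 1000 px (a 25-cm fish at
  50 cm spans 500 px of the 1920-px frame), frame 1920×1080, depth
  bounds 5–60 cm. Depth labels are quantised to the nearest 10-cm marker
  (half-up, clamped to the bounds), mirroring manual marker reading;
  `marker_spacing_cm=None` disables quantisation. Pixel measurement
  noise is additive Gaussian, SD 2 px. The depth range is exposed as two
  parameters (`depth_min_cm`, `depth_max_cm`) rather than hard-coded,
  since the observed label spread (5–50 cm) is narrower than the nominal
  5–60 cm working range.
* **Tabular sightings.** `make_file_dataset` draws sighting depths
  uniformly over the camera bounds. A sighting whose noiseless projected
  length exceeds the frame width is an invalid observation (signalled by
  `ObservationOutOfFrame` in `observe`); the table builder redraws the
  depth until the fish fits, so exactly n rows are returned and the
  marginal depth distribution is uniform conditional on visibility. With
  the default geometry this truncates depths below roughly 11–15 cm
  depending on fish size.
* **Scenes.** Fish are drawn as filled ellipses inscribed in their
  projected bounding boxes at uniform-random positions; overlap is
  allowed. Turbidity in [0, 1] applies contrast reduction (factor
  1 − 0.7t), a green cast (+60t on G), and Gaussian blur (σ = 4t), in
  that order; positions and per-fish shading are drawn before any
  turbidity effect, so the same seed yields identical annotations at any
  turbidity. The renderer does not attempt photo-realism: no fins, no
  texture, no lighting, no motion. Consequently, pixel-level results
  (e.g. the threshold detector's behaviour) characterise the algorithms
  on clean geometry, not performance on real footage; the tabular
  cascade results likewise inherit the generator's idealisations (exact
  allometry, fixed aspect ratio, unbiased pixel noise).

## Enhancement

Three operators in fixed order: per-channel 2-D correlation with an
odd-sized sharpening kernel (replicate padding); a 3×4 colour-correction
matrix acting on the normalised (R, G, B, W) vector, W = mean(R, G, B),
with offset subtraction and a 1/γ power (negative intermediates are
clipped to zero before the power); and gain/bias exposure adjustment.
The published description names the operators but not their constants,
so the defaults — unsharp kernel [[0,−1,0],[−1,5,−1],[0,−1,0]], identity
CCM, γ = 2.2, gain 1.3, bias 10 — were chosen once to visibly counteract
the synthetic turbidity model, and everything is overridable. The CCM is
read as 3×4 (three output channels from four colour spaces), covering
both the colour-filter and colour-balance roles. All images remain valid
8-bit arrays: outputs are clipped to [0, 255] and rounded to nearest
integer, ties away from zero. Frame sampling takes indices
n_k = round(k·T·fps) strictly below duration·fps, deduplicated.

## Detection seat

Network construction and training of a learned detector are out of
scope; the pipeline defines a detector protocol plus two backends. The
oracle backend replays ground truth with configurable jitter and score
noise and is the reference for end-to-end tests; the threshold backend
(Otsu binarisation, connected components, solidity scores) exercises the
pixel path. The multi-task losses — classification −ln p_u, smooth-L1
box loss, per-pixel mask cross-entropy — are implemented as pure
formulas. The printed one-term form of the mask loss is not a binary
cross-entropy; since it is described as one, the standard two-term BCE
averaged over pixels is implemented. AP uses greedy score-descending
matching (each ground truth matched at most once, ties by input order)
and 101-point interpolation averaged over IoU thresholds 0.50:0.05:0.95,
so small-case values are exactly reproducible. An empty scene with no
detections scores 1.0 by convention (logged). Boxes are 0-based,
half-open throughout. A taller-than-wide box is treated as a vertical
fish: extents are swapped and flagged rather than failing.

## Cascade details

* **Splitting.** Test rows are carved off first: pool = round(n·outer),
  then train = round(pool·inner); rounding is nearest with ties to even.
  Defaults 0.7/0.8 for tabular data reproduce the published partition
  1555/389/833 of 2777 rows (and 0.7/0.7 reproduces 2101/900/1286 of
  4287 images). The shuffle is seed-deterministic.
* **Regressors.** LR is exact least squares with intercept
  (minimum-norm with a warning when the design is rank-deficient — this
  happens by construction on default synthetic data, where width is an
  exact multiple of length). RFR defaults to 100 trees of maximum depth
  2 with bootstrap resampling. SVR is the ε-insensitive RBF machine
  (defaults C = 100, γ = "scale", ε = 0.1) inside a standardisation
  pipeline; LR/RFR see raw features. Grid search evaluates every
  Cartesian combination against validation MAE; ties keep the first
  combination in deterministic iteration order. The shipped default SVR
  grid is C ∈ {0.1, 1, 10, 100}, γ ∈ {0.001, 0.01, 0.1, 1},
  ε ∈ {0.01, 0.1, 1}.
* **Two-output centimetre stage.** Length and width are two
  independently trained single-target regressors sharing one spec.
* **Residual summaries.** Validation-split signed-residual mean/SD per
  stage are stored on the fitted estimator as the empirical counterpart
  of the additive error terms of the stage equations.
* **Nine-case grid.** Labels SSL…SLS fix the depth stage (SVR) and vary
  the centimetre and weight stages over SVR/RFR/LR; each case is a full
  retrain and is scored on the shared test split.
* **Persistence.** A versioned joblib archive holding the whole fitted
  estimator; round-trips reproduce predictions bit-exactly.

### What the synthetic results can and cannot show

With all noise sources disabled (pixel noise 0, no depth quantisation,
zero weight SD) the cascade recovers each fish's weight to well under
10%: age then determines weight exactly and the linear weight stage can
represent it. With default noise, per-fish weight is *not* identifiable
from (age, pixel dims) alone — a large distant fish and a small near
fish project identically — so accuracy is cohort-level: on the 2777-row
default table the cascade reaches depth R² ≈ 0.94 and weight R² ≈ 0.75
on the held-out split, the synthetic analogue of the published 0.87 /
0.70. These figures validate the wiring and the relative ordering of
regression families, not field performance.

### Monotonicity

In the fitted weight stage, pixel features are conditionally
uninformative given exact centimetre annotations, so their individual
coefficient signs are noise. The physically identified direction —
a jointly larger fish (pixel and centimetre dimensions scaled together
at fixed age and depth) — is verified to never decrease the predicted
weight.

## Area-based comparators

Seven closed forms map body area A = L·W·c (cm²) to weight: a fixed-3/2
power law, two free power laws, an exponential, a linear, a logarithmic,
and a quadratic. The default coefficients are the published calibration
constants; the area coefficient c is never printed and defaults to 1.0
(any constant is absorbed by the fitted coefficients). Refitting is by
ordinary least squares in each family's natural space — raw space for
linear/logarithmic/quadratic, log space for the exponential and power
families (deterministic and exact on noiseless data; on noisy data a
log-space fit differs from nonlinear least squares, which is why the
reported residual sum of squares is defined in the fitting space, where
least-squares optimality holds).

## Numerical conventions

* Rounding of image intensities: nearest, ties away from zero.
* Split-size rounding: nearest, ties to even.
* MAE ratio = MAE / R²; undefined at R² = 0 (error for the scalar
  function, NaN inside a bulk report).
* Error SD uses the sample (n−1) denominator; signed errors are
  predicted − actual, so under-prediction is negative.
* Depth labels: spacing·floor(d/spacing + 0.5), clamped to the bounds.

## Problem sizes

Default test and acceptance runs use a 2777-row table (matching the
published dataset size), 10,000-fish cohorts for calibration checks, a
few full-HD scenes for detection and end-to-end runs, and a 600-row
noiseless table for recovery runs — sizes at which every result in the
suite is stable and quick to recompute on one CPU.

## Known limitations

* The renderer's geometry is idealised; no occlusion handling beyond
  overlapping ellipses, no cross-frame identity (the score filter is
  per-frame; deduplicating the same fish across frames is out of scope).
* The cascade assumes the user-supplied age is correct; depth inference
  leans on the age-conditional size distribution, so mis-stated ages
  bias all three stages.
* Fixed width/length ratio in the generator makes the weight-stage
  design collinear; real data would break this, which is why the
  minimum-norm warning is expected on synthetic runs.
* The learned detector itself (and hence published AP scores) is not
  reproducible here; the evaluation machinery is, and is exercised via
  the shipped backends.
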