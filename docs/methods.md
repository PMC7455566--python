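# Methods notes

This note records the modelling choices behind `featdiag`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic-data generator does and does not emulate, and the
numerical conventions that make runs reproducible.

## Wavelet model

An image feature is a Gabor wavelet: a cosine grating windowed by an
isotropic Gaussian. Conventions:

- **Coordinates.** 0-based pixel indices, x = column, y = row; wavelet
  centres on pixel centres. The default geometry is 250 px spanning
  22.5 deg of visual angle (11.11 px/deg); tests and examples often use
  125 px / 11.25 deg, which keeps the same px/deg so all ladder
  frequencies stay representable.
- **Frequency ladder.** sf(n) = (10/45)·1.08^n cycles/deg for n = 1..29,
  i.e. 0.24 to 2.07 cpd. The per-level candidate count is
  nw = round(272·sf^1.8): 21 at the coarsest level, 1,008 at the finest.
  These constants are part of the stimulus model and are not re-tuned.
- **Envelope width.** The grating's Gaussian envelope is not pinned down
  by the count and frequency rules alone; we set sigma = 0.5 wavelengths
  (roughly one octave of frequency bandwidth), the common psychophysics
  convention that keeps coarse wavelets spatially extended. Configurable
  via `sigma_factor`.
- **Phase.** Continuous in [0, 2*pi), estimated from the quadrature filter
  response (arctangent of odd over even response); orientations are
  quantized to the 18-step grid, phase is not.
- **Display rescaling.** min -> 0, max -> 255 with round-half-to-even;
  this makes stimulus PNGs bit-identical across platforms. A constant
  image has no valid mapping and is an error.

## Decomposition

The coarse-to-fine loop visits the 29 ladder levels in order. Per level:
quadrature filtering (complex Gabor kernels, reflective boundary padding
to avoid edge ringing) gives per-pixel best orientation/phase/amplitude;
the top 25 % of pixels by amplitude are candidates; nw of them are sampled
uniformly without replacement (when fewer are available, all are taken and
the event logged); sampled wavelets whose covariance with the current
input is below 1/5 of the maximum observed covariance are dropped.

Numerical and interpretive choices the original recipe leaves open:

- **"Covariance"** is the sample covariance over all pixels between the
  unit-amplitude rendered wavelet and the (mean-centred) image. It is
  *signed* both in the mid-iteration discard and in the final ranking;
  a wavelet anti-correlated with the image is simply a phase-shifted
  better wavelet's inferior twin and ranks low.
- **Residual update.** The next level's input is the residual of the
  current input regressed (with intercept, guarding against DC drift) on
  the wavelets selected at the current level. Because each level's input
  is already a residual with respect to all earlier selections, this
  sequential block orthogonalisation is the natural reading of
  "regression of the input to the previous iteration"; `residual_update`
  accepts any wavelet list, so cumulative re-regression is available to
  callers who want it. Rank deficiency falls back to the minimum-norm
  solution with a logged warning.
- **Final bank.** Pooled survivors are ranked by covariance with the
  *original* image; the top `n_final` (default 1,000) are kept with a
  common amplitude. Fewer pooled candidates than `n_final` is an explicit
  error naming the shortfall. Because the bank is stored in rank order,
  the top-k prefix of a 1,000-feature bank equals a run with n_final = k.
- **Determinism.** All sampling flows through one `numpy` Generator; the
  same seed reproduces the bank exactly.

On a 20-Gabor planted image (125 px) the pipeline recovers >= 80 % of the
planted positions within 2 px, and the display-space reconstruction error
falls monotonically as the bank grows from 100 to 1,000 features; both are
asserted in the test suite.

## Trials and stimuli

A trial is a uniform random 90-of-1,000 feature subset, summed and
rescaled to 0-255. Sessions present each image 50 times in a uniformly
shuffled order. Subsets are drawn independently per trial and participant
(a shared-subset pool can be supplied instead; the original procedure does
not specify which was used). Fixation timing is experiment metadata only —
no display engine is included.

## Synthetic cohorts and the observer model

The generator's defaults are the study conditions it emulates:

| parameter | default | note |
|---|---|---|
| participants | 52 | median AQ split: high iff AQ > median |
| AQ totals | round N(14.3, 5.9) clipped to [5, 30] | neurotypical range |
| sessions | {6:2, 5:14, 4:25, 3:10, 2:1} | exact multiset when n = 52 |
| subset size / trials | 90 features, 50 trials/image/session | |
| response thresholds | correct > 0, wrong < −0.8, noise SD 1 | marginals ≈ 50/21/29 % correct/wrong/unsure |
| base weight scale | 2.0 | covariance-rank base, z-scaled |
| sf coupling (high/low AQ) | 0.2 / 0.0 | see below |
| item coupling scale | 0.3 | proportional to diagnosticity, social-skill items |
| RT | max(150, N(895 ± 95 by group, 250)) ms | carries no feature signal by default |

AQ item endorsements are drawn without replacement to match each
participant's total (Gumbel top-k weighted sampling), with the planted
(clinically diagnostic, social-skill) items loaded toward high totals, so
trait/total consistency holds exactly. The subscale partition of the 50
items is the standard five-by-ten assignment.

An observer's per-feature weight is `base + c · z(sf)`: the base follows
the feature's covariance rank (shared across observers), and the coupling
`c` grows with AQ group and with endorsement of the planted items. The
couplings were calibrated once so that a default cohort lands near the
magnitudes a human cohort of this size plausibly produces — a highest-bin
group difference of roughly 0.01–0.02 FDi z-units, interaction F in the
single digits, split-half replicability r ≈ 0.1. Evidence is the *mean*
(not sum) of presented weights so difficulty is invariant to subset size.

What the generator does **not** emulate: perceptual similarity structure
between cats and dogs (wrong-animal responses are random), sequential
effects, learning or fatigue across sessions, lapses, and any spatial
correlation between feature weights and image content. Passing recovery
tests therefore shows the estimator and statistics are correct and
well-calibrated — not that real observers behave like the generator.

The bundled trait table (`default_trait_table`) is synthetic: per-item
prevalences whose log ratios order the subscales as the AQ validation
literature does (social skill most diagnostic, attention to detail least)
with the canonical top item at ln(7.7) = 2.04. Real prevalence data can be
supplied as a CSV (`item_id, subscale, prevalence_asd, prevalence_control`
or a `prevalence_ratio` column).

## FDi estimation

- Per-feature accuracy marks unsure and wrong-animal responses as 0;
  cells never shown are missing, and after z-scoring they are imputed as 0
  (logged). At 200 trials/image and 90/1,000 subsets the expected count
  per cell is 18 and missing cells are vanishingly rare.
- Z-scoring uses the sample (n−1) SD, configurable. A constant slice is
  uninformative and becomes zeros with a warning.
- Split-half replicability partitions participants into halves of size
  ceil(n/2)/floor(n/2), 100 splits by default. The permutation null reuses
  the observed splits and permutes one half's flattened feature vector,
  one fresh permutation per iteration; p uses the add-one estimator so it
  is never 0. Implementation note: correlations across all
  (split, permutation) pairs reduce to a single F × F cross-split Gram
  matrix plus one fancy-indexed trace per permutation, which makes 10,000
  permutations on 10,000-feature vectors take seconds.
- Because the splits overlap across iterations while the null permutes
  only feature labels, the permutation p is slightly over-dispersed under
  a global null at small cohort sizes (≈ 10 % of null cohorts fall below
  0.05 instead of 5 %); it is centred correctly and the effect shrinks
  with participants × features. The calibration tests assert the
  tolerance accordingly.
- The RT variant replaces accuracy with per-feature mean RT over all
  trials (a flag restricts to recognized trials; whether the original
  analysis filtered is unknown).

## Bin ANOVAs

Features from all images are pooled, stably sorted by the criterion
(spatial frequency, nearest-eye distance, centre distance — distances in
deg of visual angle), and cut into five equal contiguous bins; ties break
by (image, feature) index so the assignment is deterministic.

Two interaction tests are provided, and the difference matters:

- `model="flat"` treats every (participant, bin) mean as an independent
  observation and fits a fixed-effects two-way ANOVA with Type II sums of
  squares. This reproduces the degrees-of-freedom pattern under which such
  analyses are usually reported (interaction df (4, 250) for 52
  participants, (1, 100) for the 2 × 2 recognition table). It is the
  pipeline default for that reason. However, z-scored FDi forces each
  participant's five bin means to sum to zero, so the flat error term
  (0.8 of the contrast variance) is too small and the interaction test
  runs hot — about 10 % rejections at nominal 5 % under the null.
- `model="rm"` fits the proper mixed repeated-measures ANOVA (within
  factor bin, between factor group; df (4, 200) at n = 52). The induced
  compound symmetry satisfies sphericity, and the test is exact at its
  nominal level (verified over 200 null cohorts). Simulation-based
  calibration and power tests use this model.

The highest-bin contrast is a pooled-variance two-sample t
(df = n1 + n2 − 2; Welch behind a flag).

## Trait statistics

Reliance-on-detail is the OLS slope of a participant's five bin means on
bin index. A trait's effect is the endorsers-minus-non-endorsers mean
reliance difference; items endorsed by everyone or no one are undefined
(NaN, logged) — the robust regression drops them pairwise, and the
subscale ANOVA (which needs the balanced 5 × 10 layout) is skipped with a
recorded reason when any are undefined, which only happens in very small
cohorts. The robust regression is IRLS with Tukey bisquare weights at the
standard tuning constant; the estimator behind the original analysis is
not documented, so this choice is flagged prominently: on clean linear
data it coincides with OLS, and t = slope / robust SE with df = n − 2.
Subscale post-hocs are each-type-vs-rest pooled t tests (df 48) with
Bonferroni correction times five, capped at 1.

## Problem sizes used by the test suite

Unit tests run on 96–125 px geometries (same px/deg as the default) and
cohorts of 8–13 participants with 150–500-feature banks. The end-to-end
recovery and power checks use full 52-participant cohorts on ten
1,000-feature simulated banks with 50–200 trials per image; null
calibration uses 200 reduced cohorts (13 participants, 2 images, 500
features). These sizes were chosen so the full suite exercises every
claim at meaningful statistical resolution while remaining comfortable to
run on a laptop core.

## Known limitations

- The decomposition is a greedy randomized selector, not an optimal
  sparse coder; two seeds give different (equally valid) banks.
- `random_feature_bank` samples wavelet positions uniformly; real
  image-derived banks concentrate features on structure, which slightly
  changes bin boundaries relative to decomposed banks.
- The flat ANOVA's miscalibration under the sum-to-zero constraint is
  inherent to that model; it is retained only for df-pattern fidelity.
- Only square grayscale images and the Gabor dictionary are supported.
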