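# Methods

`exporf` implements a six-stage workflow for identifying longitudinal
exposome-related predictors of a binary health outcome with a random
forest, together with a synthetic-cohort generator that provides ground
truth for validating every stage. This note records the model, its
conventions, the tunable parameters, and the numerical choices, in the
order the pipeline runs them.

## Trajectory summaries (AUE and TOE)

Each exposure measured in several rounds is reduced, per subject, to two
numbers computed on the *observed* rounds only, so subjects with missed
visits stay in the analysis.

**Continuous exposures.** For observations (r_1, v_1), ..., (r_k, v_k)
with r_1 < ... < r_k:

- AUE (area-under-the-exposure) is the time-average of the
  piecewise-linear interpolant: the trapezoidal area between r_1 and r_k
  divided by the span r_k − r_1. Dividing by the span makes exposures
  observed over different numbers of rounds comparable; for a linear
  trajectory v(r) = a + b·r it equals a + b·(r_1 + r_k)/2.
- TOE (trend-of-the-exposure) is the unweighted mean of the per-pair
  slopes (v_{i+1} − v_i)/(r_{i+1} − r_i). With unequally spaced observed
  rounds this differs from the end-to-end slope; the unweighted mean is
  used because each between-round change is treated as one observation of
  the subject's trend.
- A single observation yields AUE = that value and TOE = 0, keeping the
  subject in the feature table.

**Categorical exposures.** AUE is the proportion of observed rounds spent
in a configured state set (e.g. % of the time married); TOE is the
indicator that a reference-state observation is followed, at any later
observed round, by a target-state observation (e.g. married → widowed or
divorced). The indicator is direction-sensitive: target before reference
scores 0. A single transition fires the indicator; repeat transitions are
not counted.

**Single-round exposures** pass through as raw features (for categorical
ones, the indicator of membership in the configured state set).

Subjects with zero observations for an exposure are flagged in a missing
mask and imputed with the cohort median (continuous-valued features) or
mode (indicator features); imputation counts are logged. The imputation
rule is deliberately simple — the masked entries let users substitute
anything better.

## Random forest

The classifier is an ensemble of `ntree` CART trees, each grown on a
bootstrap sample of the training subjects with `mtry` candidate features
per split, at least `nodesize` observations per terminal node, and at most
`maxnodes` terminal nodes (unbounded by default). The predicted risk is
the fraction of trees casting a hard class vote for the positive (poor
health) class, so predictions are multiples of 1/ntree; leaf probabilities
are never averaged. Out-of-bag (OOB) membership is recorded per tree and
coverage below 99% of subjects triggers a warning.

Trees are scikit-learn `DecisionTreeClassifier`s; the bagging loop and OOB
bookkeeping are explicit so the bootstrap stream is fully controlled by
the run seed (every stochastic stage draws from a named substream of the
single run seed; see `_rng.py`).

**Split.** Subjects are split into train/test (default 80/20) with
class-stratified, largest-remainder rounding; both classes keep at least
one member on each side.

**Tuning.** A grid search over (`mtry`, `ntree`, `nodesize`, `maxnodes`)
with stratified k-fold cross-validation (default 5 folds) on the training
split maximizes mean out-of-fold AUC. The default grid is
mtry ∈ {⌊√p⌋, ⌊p/5⌋, ⌊p/3⌋}, ntree ∈ {500, 1000}, nodesize ∈ {1, 5, 10},
maxnodes ∈ {unbounded, 64, 256}. The fold assignment and per-fold tree
seeds are shared across grid points, so permuting the grid cannot change
the selection; exact-AUC ties break toward the cheapest, most regularized
model (smallest ntree, then largest nodesize, then smallest mtry, then
smallest maxnodes with unbounded last). Accuracy is reported but never
optimized.

## Permutation importance and feature-count selection

**MDA.** The importance of feature j is the mean decrease in accuracy:
for each tree, accuracy on its OOB subjects minus accuracy on the same
subjects after column j is freshly permuted (one permutation per tree per
feature; repeats configurable), averaged over trees. Values are raw and
unscaled, staying in accuracy units; a feature no tree splits on scores
exactly 0, and noise features may go slightly negative. The ranking sorts
by descending MDA with ties broken lexicographically by feature id.

By default the ranking is computed on the training split only, so the
held-out evaluation of the reduced model stays valid. Setting
`RunConfig.importance_on = "full"` refits on the entire dataset for the
ranking (the display-oriented variant), with a logged warning that the
reduced-model test AUC then becomes optimistic.

**Selecting q.** The number of retained top-ranked features q is treated
as a tuning parameter: for each candidate q, the forest is refit on the
top-q features (mtry capped at q) under k-fold CV with the previously
selected hyperparameters, using one shared fold assignment. The curve of
CV AUC against q typically rises steeply and then flattens; "flattening"
is operationalized as the smallest q whose CV AUC is within ε (default
0.005 AUC units) of the curve maximum. The full curve is always written
out so the visual choice can be overridden. ε trades parsimony against
performance; larger ε never selects a larger q.

## Effect curves

**PDP.** For grid value g (50 equally spaced points between the 5th and
95th empirical percentiles; exact observed levels for features with ≤ 10
unique values), the effect is the mean predicted risk with every subject's
value of the feature forced to g and all other features at their own
values. The curve object stores the outcome prevalence as a reference
level for plotting.

**ALE.** The feature's clipped support is cut into empirical quantile bins
(default 20; duplicate edges from ties are merged and logged). The local
effect of bin k is the mean prediction difference between the bin's upper
and lower edge over the subjects *inside* that bin, which avoids
extrapolating into feature combinations that never occur. Local effects
are accumulated across bins and centered by subtracting the mean of the
accumulated curve interpolated at each subject's own value, so the
data-weighted mean of the curve is zero. (Centering at each subject's bin
edge instead would bias the curve by half a bin width — about 0.07 at 20
bins on a unit-range feature — which is why interpolation is used.)
Indicator features fall back to a centered two-level difference.

For additive prediction functions PDP and ALE agree up to an additive
constant; `curve_concordance` quantifies the sign agreement of their
slopes on the shared grid.

## Evaluation

The AUC is the Mann-Whitney probability that a random positive outscores
a random negative, ties counted 1/2. Its 95% CI uses the DeLong
structural-components variance with a normal approximation, truncated to
[0, 1] (a stratified percentile bootstrap is available as a cross-check;
the method choice is a package convention). The "optimal" ROC threshold maximizes
sensitivity + specificity (Youden), scanning midpoints between adjacent
distinct scores plus the boundaries; ties (compared after rounding to 12
decimals) break toward the smaller threshold, favoring sensitivity.
Sensitivity, specificity and accuracy at the fixed 0.5 threshold are also
reported. Calibration-in-the-large compares mean predicted risk with
observed prevalence; the calibration curve uses quantile decile bins with
tied edges merged.

**Domain ablation** refits the pipeline once per exposome domain with that
domain's features removed, on the same split and with shared seeds across
variants (so ablating an empty domain reproduces the total row exactly).
Each variant re-runs the grid search by default (`ablation_retune`),
which is conservative; the total model's parameters can be reused instead.

## Synthetic cohorts

The generator emulates the structure of a five-round population cohort
with a binary outcome at round 6: by default 3419 subjects, 45 multi-round
exposures (39 continuous, 6 categorical) plus 6 single-round exposures
across the four exposome domains, yielding exactly 96 summary features;
~16% outcome prevalence; and round-dependent missingness.

- Continuous trajectories follow a random-intercept/random-slope model
  with independent within-subject noise, the simplest generator whose true
  AUE and TOE map directly onto the latent intercept and slope (users can
  extend to AR(1) noise).
- Categorical exposures evolve as Markov chains with row-stochastic
  per-round transition matrices.
- The outcome is Bernoulli with log-odds = intercept + Σ planted effects
  of the *true* (pre-missingness) summaries, standardized per feature.
  Effect shapes are linear (β·z), threshold (β·1[z > 0.5]) and U-shaped
  (β·(z² − 1)/√2). Because the outcome depends only on true trajectory
  summaries, AUE/TOE is the correct feature representation by
  construction — this is the validation premise, stated openly.
- The intercept is solved by bisection so the mean outcome probability
  hits the target prevalence (or can be fixed directly).
- Missingness: a monotone per-round dropout hazard (optionally
  outcome-linked, off by default) plus record-level MCAR rates rising with
  round (defaults 2–12%). The outcome is never missing.

The default nine planted signals mix AUE, TOE, a state-occupancy
proportion, a transition indicator, a single-round raw score, one U-shaped
and one thresholded effect, spread over all four domains, with |β| between
0.45 and 0.55 per SD (odds ratios ≈ 1.6–1.75 per SD). These magnitudes
were fixed by a power simulation so that the pipeline recovers at least
7 of 9 planted features at study scale in nearly every seed — i.e. the
defaults describe strong but epidemiologically plausible predictors. At
these settings the full-model held-out AUC lands around 0.67–0.70.

**What the generator does not emulate:** real marginal distributions and
units of the exposures beyond rough scales, between-exposure correlation
structure (exposures are generated independently), informative
missingness by default, measurement error models, or non-proportional
trajectory shapes. Passing tests therefore demonstrate that the pipeline
recovers planted longitudinal structure under its own assumptions, not
that it would rank any particular real exposure highly.

## Problem sizes and numerical conventions

- Desk-scale runs in the test suite and acceptance script use ntree = 200,
  2–3 CV folds, compact tuning grids (1–2 points) and a 10-point q ladder;
  these are the package's documented desk-scale choices, while the library
  defaults above match the full-scale setup.
- The null-importance check uses a 50/50 train/test split: the null-AUC
  standard error at a 400-subject test set (~0.029) would make a ±0.05
  chance band a ~1.7σ statement, while 1000 test subjects (~0.018) make it
  ~3σ per seed.
- All randomness flows from one run seed through named substreams
  (`_rng.stage_seed`), so any stage reproduces in isolation and full runs
  are byte-identical across repeats; result CSVs print floats to 12
  significant digits.
- Degenerate inputs: zero-variance features yield a single-point PDP with
  a warning; tied quantile edges merge bins (ALE, calibration); classes
  too small to stratify raise errors rather than degrade silently.

## Known limitations

- MDA is computed per tree with one permutation; conditional or
  correlation-adjusted importance, importance p-values, class-imbalance
  resampling, probability calibration post-processing, alternative
  learners, 2-D interaction curves, ICE and SHAP are out of scope.
- The ε-flattening rule is a reproducible stand-in for a visual judgement;
  the emitted q-curve is the authoritative artifact.
- Trained forests are not serialized; they are refit deterministically
  from the recorded seed and config in the manifest.
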