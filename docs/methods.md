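# Methods

## Model and assumptions

The package targets ordinal classification of an outcome y ∈ {C₁ < … <
C_K} from mixed categorical/continuous predictors under severe class
imbalance. The core method assumes only that a probabilistic classifier
can be trained per one-vs-all target and that a held-out fold is
available for calibration; it makes no parametric assumption about the
feature–outcome relationship. Ordering enters in three places: the
cumulative construction p̂(y > C_k) = Σ_{j>k} p̂(y = C_j), which is
non-increasing in k for any probability row (rank monotonicity holds by
construction, not as an empirical property); the exceedance-count
decision rule; and the contiguous category-combination schemes.

Rank *consistency* (unimodal per-class probability profiles) is not
enforced on the class probabilities themselves — one-vs-all models can
and do produce non-unimodal rows — and the pipeline's guarantee lives
entirely in cumulative space. The tests document this distinction.

## Pipeline stages and their parameters

**Base learners.** Any estimator with `fit`/`predict_proba` works; the
default is gradient-boosted trees (300 trees, depth 6, learning rate
0.1, subsample 0.8, single-threaded histogram method), with a lighter
`xgboost_fast` preset (200 trees, depth 4) used for repeated benchmark
runs, plus logistic, MLP (64/10 ReLU) and RBF-SVM alternatives. No
hyperparameter search is performed: the meta-method, not learner tuning,
is the subject. Categorical features are passed to tree learners as
integer codes; a one-hot transform exists for encoding-sensitive
learners. Refitting with the same seed and data reproduces identical
predictions.

**Category combination.** All contiguous ordered partitions of K levels
into G classes are enumerated as cut tuples (C(K−1, G−1) of them; six
for K=5, G=3). The lowest level always maps to class 1 and the highest
to class G. A published-numbering alias table is provided; only two of
its six entries are pinned by unambiguous descriptions, the rest are
best-effort and overridable, so schemes are canonically identified by
their cut pair.

**SMOTE-NC oversampling.** Classes with fewer than `threshold_fraction`
(default 0.20) of the majority count are grown to
`round(target_fraction × majority)` (default 0.20). Distances between
minority instances are squared Euclidean on continuous features
standardized by training-fold statistics, plus a per-categorical-
mismatch penalty equal to the squared median of the minority class's
(standardized) continuous standard deviations. Synthetic rows
interpolate continuous coordinates uniformly between a parent and one of
its k = 5 nearest minority neighbors and take the majority category
among those k neighbors (ties to the lowest code). Oversampling is
append-only, runs inside cross-validation on training folds only, and is
reproducible from its seed. A class of size ≤ k shrinks k to size − 1
with a warning; a singleton class is an error.

**Calibration.** Isotonic regression (default): the monotone
least-squares fit of the binary one-vs-rest outcome on the raw score,
represented as a piecewise-constant non-decreasing map whose bin
boundaries are midpoints between adjacent training scores of different
fitted values. Applying the K maps breaks the simplex constraint, so
rows are renormalized afterwards; this is the simplest reconciliation
that restores a probability vector, at the cost of slightly perturbing
each column's individual calibration. Platt scaling (logistic fit of
outcome on score) is available for small calibration sets but is not the
default, isotonic being preferable at the calibration-fold sizes the
protocol produces. All-identical outcomes yield a constant map with a
warning.

**Threshold search.** For each cut k independently, T_k maximizes the
calibration-fold F1 of predicting y > C_k by 1{p̂(y > C_k) > T}, over
the grid {0.01, …, 0.99}; ties go to the smallest threshold, and 0.5 is
on the grid, so the selected threshold never has lower validation F1
than the default. A cut with no positive validation examples falls back
to T = 0.5 with a warning. A joint coordinate-ascent search maximizing
macro-F1 of the full ordinal prediction is available behind a flag
(`joint=True`); measured on the benchmark below it changes results only
marginally, so the simpler per-cut search is the default. The single
calibration fold serves both calibration and threshold search,
sequentially.

**Evaluation protocol.** Stratified 10-fold cross-validation with an
8/1/1 rotation: fold j tests, fold j+1 calibrates, the remaining eight
train (with oversampling when triggered). Methods that need no
calibration fold simply leave it unused, keeping training sets identical
across methods. The driver asserts the three index sets are disjoint —
sampling, calibration and threshold search never see test rows.
Zero-denominator precision/recall is reported as 0 with a warning.

**Classifier comparison.** The 5×2 cross-validated paired t-test:
five seeded 2-fold splits, per-fold score differences Δᵢ⁽ʲ⁾, statistic
t = Δ₁⁽¹⁾ / √(mean of per-repetition variances), referred two-sided to
t with 5 degrees of freedom (95% critical value 2.571). A
"first_repetition" variant that centers every squared deviation on the
first repetition's mean and uses that mean as numerator is provided
behind a flag, but the standard form is the default because it is the
form with the documented sampling behavior. Identical methods give
(t, p) = (0, 1); a fold on which the metric is undefined triggers a
seeded re-draw. The default comparison metric is accuracy; macro-F1 is
available. Measured type-I error at α = 0.05 over 200 null replicates:
0.02–0.03, within the test's documented slightly conservative range.

## Synthetic data

The generator emulates the statistical shape of crash-severity records:
3 continuous features (standard normal) and 14 categorical features with
cardinalities (2,2,2,2,3,3,4,4,5,6,6,8,9,12), class shares defaulting to
(57.2, 29.6, 10.8, 1.93, 0.47)%, and an ordered-logit latent structure —
latent score = weighted feature sum (categorical level c of a feature
with weight w contributes w·linspace(−1,1)[c], so codes act
monotonically) plus logistic noise, thresholded at empirical quantiles
so class shares match the configuration. Default weights decay
geometrically with a clearly dominant first continuous feature, giving
the permutation-importance machinery a known ground truth. The
calibration stress generator additionally returns the exact class
probabilities each label was drawn from, plus a copy distorted by a
user-supplied monotone map, so calibration error and its removal can be
scored against ground truth.

What the generator does **not** emulate: real crash-data semantics,
feature dependence/interactions, label noise that is non-logistic, or
the particular miscalibration profile of any real classifier. Passing
tests therefore demonstrate correctness of the machinery and behavior on
clean ordinal data, not performance claims about real crash records.

**Reliability summaries** use the count-weighted mean absolute bin
deviation (expected calibration error, 10 equal-width bins by default).
For rare classes, unweighted bin means are dominated by near-empty
high-probability bins whose deviations are pure sampling noise — at
N = 10⁵ the 0.47% class has only a handful of samples above p = 0.5 —
so occupancy weighting is the statistically meaningful summary. Measured
on a square-root distortion at N = 10⁵ (overestimating small
probabilities, the typical rare-class pathology), per-class isotonic
maps fitted on half the data cut the weighted deviation on the other
half by ~92%.

## Numerical choices

- Labels are integers 1..K everywhere; cut indices are 1-based.
- Argmax ties and exceedance counts break toward the lower (less
  severe) class; threshold-grid ties take the smallest threshold.
- The Beckham continuous score maps to a class by round-half-down,
  clipped to [1, K]. The fitted-weight variant minimizes the sum of
  squared rank errors by least squares (the only well-posed reading of
  the objective); rank-deficient designs get the minimum-norm solution
  with a warning. Weights are fitted on the calibration fold, not
  training predictions (configurable).
- Frank differencing keeps negative middle probabilities raw — they are
  the benchmark's documented weakness, and clipping would mask it.
- Cumulative construction renormalizes rows and rejects rows with
  non-finite or near-zero mass (< 10⁻³).
- Probability-row simplex tolerance is 10⁻⁶; monotonicity checks use
  10⁻¹².
- Generator cut points are sample quantiles, so configured class
  proportions are matched to within integer rounding at any N; a class
  with expected count < 2 is rejected.

## Known limitations

- **F1 threshold moving trades precision for recall on calibrated
  probabilities.** The 20-seed benchmark in `scripts/acceptance.py`
  (N = 20,000, strong effects, 5 levels merged by cuts (1,3), SMOTE-NC,
  equal gradient-boosted learners) shows the mechanism cleanly: raw
  one-vs-all minority probabilities are overestimated after
  oversampling, and calibrated argmax beats the nominal baseline on
  macro precision; but the F1-optimal thresholds the method then adopts
  sit near maxF1/2 (≈ 0.3 for the rare class), which raises minority
  recall at the cost of precision and rank error. On cleanly simulated
  latent-threshold data the nominal baseline consequently retains a
  small macro-precision and rank-error edge on average, while the
  ordinal method wins on minority recall and, on harder configurations,
  minority F1. Gains reported on real crash data depend on the severity
  of real-classifier miscalibration, which clean simulation
  under-represents.
- The published numbering of four of the six category-combination
  schemes is not recoverable from their descriptions; the alias table is
  explicit about which entries are guesses.
- Isotonic calibration can overfit small calibration folds (step maps
  from few positives); Platt scaling is the intended fallback there.
- The 5×2cv test is approximate; its statistic is not exactly
  t-distributed, and the measured type-I error is mildly conservative.
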