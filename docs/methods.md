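# Methods

## The prediction problem

An odorant molecule, presented at a known dilution, elicits ratings on a
0–100 scale for 21 perceptual attributes — intensity, pleasantness, and 19
semantic descriptors (garlic, sweet, fish, ...) — from a panel of untrained
subjects. The task is to predict these ratings for unseen molecules from
large-scale chemoinformatic descriptors (a Dragon-style molecules ×
features table) and, optionally, from the molecule's chemical name. Two
prediction scopes matter: *individual* (one prediction per subject) and
*population* (the panel mean).

The central obstacles are (i) enormous rater-to-rater variability — raters
differ both in bias (some saturate the top of the scale, some compress
toward the middle) and in per-stimulus noise — and (ii) a feature space
(~4884 descriptors in the reference study) an order of magnitude larger
than the molecule sample (~400 training molecules), with a structure-odor
map that is strongly nonlinear.

## Model

### Per-(subject, attribute) random forests

One random-forest regressor (100 trees; otherwise scikit-learn defaults)
is trained for every combination of subject and attribute — 49 × 21 = 1029
models in the reference configuration — plus one population model per
attribute. Forests suit the regime: they tolerate p ≫ n, capture
nonlinearity and feature interactions, and are robust to label noise.
Linear, ridge (α = 10), and SVR (rbf, C = 1000, γ = 0.01) baselines are
available through the same interface for comparison.

### Individual/population target blending

Each individual model's training target is the convex combination

    y = α · y_individual + (1 − α) · y_population,    α ∈ [0, 1]

with `y_population` the across-subject mean rating of the same stimulus
and `α = 0.2` by default. Pulling targets toward the panel mean suppresses
rater noise while preserving a personalized component; α = 0 reduces to
population-only targets, α = 1 to purely individual ones. Blending is
monotone in α, and its benefit under heavy noise is one of the
experiments in `odorforest.experiments`.

### Name fingerprints

A 4-character window slid over the normalized chemical name (uppercased;
runs of non-alphanumerics collapsed to `_`) yields binary "name features"
that act as a crude structural fingerprint. The default window rule
(`mode="strict"`) skips windows whose second character is the separator,
which reproduces the published seven-window worked example for
"acetic acid" exactly; `mode="naive"` enumerates every contiguous window.
The exclusion rule is reverse-engineered from that single example, so both
behaviors are first-class and flag-selectable. Vocabularies are always fit
on training names only. Predictions from descriptor-based and name-based
model matrices are combined by weighted averaging (default equal
weights). Feature concatenation is possible instead — `train_model_matrix`
accepts any molecules × features frame, including a concatenated one —
but averaging is the default because it keeps the two feature families'
models independently interpretable, and the aggregation rule is a choice
the source study leaves open.

### Permutation delta-error importance

The importance of a feature for an attribute is the increase in mean
squared error when that feature's values are permuted across evaluation
molecules (mean over `repeats` shuffles, default 10), measured on a
held-out evaluation split of the population-level targets (25% of
stimuli, seeded). Held-out MSE was chosen over out-of-bag error because
it is well-defined for any regressor backend and reproducible. A constant
column has exactly zero delta error. A parallel ranking by |Pearson r|
exposes the contrast between what the forest uses and what correlates
linearly: correlation ranking surfaces collinear, redundant feature
clusters, delta-error ranking does not. `retrain_top_k` re-runs the whole
cross-validated pipeline on the top-k features to quantify how few
features suffice.

## Preprocessing

* Missing ratings are dropped. An odorless presentation is recorded as
  intensity 0 with all other attributes missing, so its intensity record
  survives.
* Intensity examples come from presentations at the "1/1,000" dilution
  (label matching is exact after stripping commas and whitespace, so
  "1/1000" is equivalent; when a table has no dilution strings the label
  is matched against the high/low concentration column instead).
* Every other attribute contributes the high-concentration rating as one
  example and, when both concentrations were rated, the high/low mean as
  a second example — doubling the sample. When only the low rating
  exists, nothing is emitted: no target is fabricated.
* Replicated molecules remain separate examples everywhere (they are
  ~5% of the reference training set) and share their partner's cid, which
  also pins them to the same CV fold.
* Descriptors are min–max scaled per column, x′ = (x − min x)/(max x − min x),
  with extrema fitted on training molecules only. Constant columns map to
  0; missing cells are imputed with the training-column median before
  scaling (forests need complete inputs); test values outside the
  training range are deliberately *not* clipped, preserving monotonicity.

## Evaluation

Molecules — not stimulus presentations — are partitioned into k = 5
seeded folds of near-equal size. Within each fold the scaler, name
vocabulary, population targets, and all models are fitted on training
molecules only; a leakage test asserts that perturbing held-out rows
cannot change any fitted state. Each attribute is scored by Pearson's r
between observed and predicted ratings pooled over (molecule, subject)
pairs; per-subject averaging is available as a flag (the pooling unit is
a genuine free choice; pooled scoring is the default because it is
well-defined even for subjects with few rated test stimuli). The observed
value scored against mirrors the example definition: the
high-concentration rating, or the configured-dilution rating for
intensity. Degenerate folds (constant observations, fewer than 2 pairs)
score as missing with a warning rather than poisoning aggregates.

Inter-rater variability is summarized per attribute by the coefficient of
variation: across-subject sd/mean per stimulus (sample sd, n − 1),
averaged over stimuli with positive mean.

Determinism: all forests derive their seeds from one base seed and the
attribute name. Seeds deliberately do not depend on the subject: with
α = 0 every subject's model shares its targets and must come out
identical, which also makes the two population-prediction modes coincide
when there is a single subject. Fixed seeds make train → predict → score
bit-reproducible.

## The synthetic study generator

`odorforest.synthetic` generates complete studies with the challenge
dataset's structure — defaults: 476 molecules (20 replicated), 49
subjects, 21 attributes, 2 concentrations, hence (476 + 20) × 2 = 992
stimulus rows per subject — so the pipeline builds and tests with no
download. What it emulates, and the parameter choices:

* **Planted structure–percept map.** Each attribute's latent percept is
  100 · sigmoid(1.3 · (zᵀw + 0.6 · z_i z_j − shift)) over 5 disjoint
  informative descriptors (standardized), with signed weights drawn with
  |w| ∈ [0.5, 1] and normalized — every planted feature carries
  non-negligible signal — plus one pairwise interaction so forests have
  an edge a linear model cannot close. The remaining descriptors are
  continuous noise and low-cardinality (≤ 10 distinct values)
  "degenerate" integer features mimicking atom-count-style descriptors.
  Columns arrive shuffled and on heterogeneous raw scales to exercise the
  scaler.
* **Rater archetypes.** Subjects are uniform raters (identity transform),
  high-saturators (concave map 100 · (x/100)^0.45 pushing mass toward
  100), or mid-centered raters (50 + 0.45 · (x − 50)), mixed
  0.4/0.3/0.3, plus i.i.d. Gaussian noise (sd 25 on the 0–100 scale,
  clipped) per rating. With 49 raters the population mean then has a
  standard error of ≈ 3.6 — noisy individuals, stable population.
* **Odorless stimuli** (10% of molecules): intensity exactly 0, all other
  attributes missing — the missingness pattern the preprocessing must
  survive.
* **Concentration structure.** Ratings attenuate at low concentration
  (×0.7; intensity ×0.6); 15% of molecules have their intensity ordering
  inverted, reproducing the monotonicity violations seen in untrained
  panels. The low presentation carries the "1/1,000" dilution label used
  for intensity modeling.
* **Names.** Pronounceable pseudo-chemical names; molecules strongly
  expressing a semantic attribute (latent > 55) embed that attribute's
  4-letter token, so name windows carry real signal.

What it does **not** emulate: real Dragon descriptor distributions or
block structure, correlated descriptor clusters, within-subject drift,
culture- or experience-dependent semantics, and any chemistry. Passing
tests therefore demonstrate that the pipeline recovers the structure this
generator plants under realistic noise — not performance on the real
challenge data, whose headline scores require the actual dataset.

## Reproducibility experiments and problem sizes

`odorforest.experiments` re-derives the method's qualitative findings;
`scripts/acceptance.py` runs them and writes the numbers. Sizes are the
package's benchmark choices:

* *Importance recovery* keeps the full default panel (476 × 500, 5
  planted per attribute) and evaluates a deterministic rotating pair of
  attributes per seed over 10 seeds (20 attribute instances), permutation
  repeats 5. Success = top-5 delta error contains ≥ 4 of 5 planted
  features.
* *Top-k economy*: 80 molecules, 6 subjects, 6 attributes, 120
  descriptors; full-feature 5-fold CV vs per-attribute top-5 retrains.
* *Blending contrast*: 40 molecules, 8 subjects, 3 attributes, 30
  descriptors, rating noise sd 35 (the heavy-noise condition), α = 0.2
  vs α = 1.0, paired over 10 seeds.
* *Learner contrast*: 50 molecules, 5 subjects, 3 attributes, 30
  descriptors, default noise; random forest vs linear, paired over 3
  seeds.

## Numerical choices and edge cases

* Ratings and predictions are hard-bounded to [0, 100]; prediction
  tensors clip at construction.
* Correlation ranking treats zero-variance features (and targets) as
  r = 0, never NaN; ties keep column order via stable sorts.
* Pearson scoring drops pairs with a missing member, requires ≥ 2
  complete pairs, and returns missing for constant vectors.
* (subject, attribute) pairs with fewer than 5 training examples are
  skipped with a warning; their predictions fall back to the population
  model, then to the training-set attribute mean.
* Permutation importance batches many (feature, repeat) permutations
  into single `predict` calls (capped at ~2M rows per call) — a pure
  speed optimization with identical results to the naive loop.

## Known limitations

* The name-window exclusion rule is inferred from one printed example;
  real name fingerprints may differ if the original rule was different.
* The published challenge files' exact column layout is not documented in
  the source study; the `challenge` reader dialect is best-effort.
* The aggregation rule of the molecular+name ensemble and the
  population predictor are not fully specified in the source study; the
  alternatives (prediction averaging vs feature concatenation;
  population model vs averaged individual predictions) are all reachable
  through the API, with the minimal reading as default.
* SVR and ridge baselines are provided for comparison only; no
  hyperparameter search is performed anywhere.
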