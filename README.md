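# odorforest

Personalized odor-perception prediction from large-scale chemoinformatic
features.

Given a panel study — molecules rated 0–100 by many subjects on 21
perceptual attributes (intensity, pleasantness, and 19 semantic
descriptors such as *garlic* or *sweet*) — and a molecules × descriptors
table of Dragon-style chemical features, `odorforest` trains one random
forest per (subject, attribute) pair and predicts both individual and
population (panel-mean) responses for unseen molecules. It is a working
re-implementation of the approach that won the DREAM olfaction
prediction challenge's individual-perception subchallenge, for
researchers in olfactory psychophysics and QSAR modelling who want a
tested, scriptable version of that pipeline.

## The method in brief

* **Model matrix.** One 100-tree random-forest regressor per
  (subject, attribute) — 49 × 21 = 1029 in the reference configuration —
  plus one population model per attribute. Linear, ridge (α = 10) and
  SVR (rbf, C = 1000, γ = 0.01) baselines share the interface.
* **Target blending.** Each individual model trains on
  `y = α·y_individual + (1 − α)·y_population` with α = 0.2: leaning on
  the stable panel mean damps rater noise while keeping predictions
  personalized.
* **Preprocessing.** Missing ratings dropped (odorless stimuli keep
  their intensity-0 record); intensity modelled from the "1/1,000"
  dilution; every other attribute gets the high-concentration rating
  plus the high/low mean as a second example (doubling the sample);
  descriptors min–max scaled, `x′ = (x − min x)/(max x − min x)`, with
  extrema fitted on training molecules only.
* **Name fingerprints.** Binary presence features from 4-character
  sliding windows of the normalized chemical name ("acetic acid" →
  ACET, CETI, ETIC, TIC_, IC_A, _ACI, ACID); descriptor-based and
  name-based predictions are ensembled by weighted averaging.
* **Feature importance.** Permutation *delta error* — the rise in
  held-out MSE when one feature's values are shuffled — ranked against a
  plain |Pearson r| ranking, with top-k retraining to show how few
  features suffice.
* **Evaluation.** 5-fold cross-validation partitioning molecules (both
  concentrations and replicates travel together), scored per attribute
  by Pearson's r between observed and predicted ratings.

A seeded synthetic-study generator reproduces the challenge data's
structure (476 molecules, 20 replicated, 49 subjects, 2 concentrations —
992 stimuli per subject), including rater-bias archetypes, odorless-
stimulus missingness, and planted informative descriptors, so everything
builds and tests without any download. The real challenge data can be
supplied in the same tabular formats but is never required. See
`docs/methods.md` for the full model description and parameter choices.

## Worked example

Generate a small synthetic study, cross-validate the blended random
forest, and report per-attribute scores:

```python
from odorforest import PanelConfig, generate, align
from odorforest.evaluate import make_cv_plan, cross_validate
from odorforest.model import LearnerSpec, BlendSpec

study = generate(PanelConfig(seed=7, n_molecules=60, n_replicated=6,
                             n_subjects=6, n_attributes=6,
                             n_descriptors=60, noise_sd=20.0))
data = align(study.ratings, study.descriptors, study.names)
plan = make_cv_plan(data.cids, k=5, seed=0)
scores = cross_validate(data, spec=LearnerSpec(seed=0),
                        blend=BlendSpec(alpha=0.2), plan=plan)
print(scores.mean_by_attribute().round(3))
print("overall mean r:", round(scores.overall_mean(), 3))
```

```
attribute
intensity       0.400
pleasantness    0.321
bakery          0.370
sweet           0.300
fruit           0.313
fish            0.538
Name: pearson_r, dtype: float64
overall mean r: 0.373
```

Each number is the mean, over the five held-out folds, of the Pearson
correlation between predicted and observed ratings pooled over the
fold's (molecule, subject) pairs — around 0.3–0.5 here because the
simulated raters add heavy noise (sd 20 on a 0–100 scale) on top of the
planted structure–percept signal. `study.truth` holds the generator's
ground truth (which descriptors drive which attribute), which is what
the importance machinery is tested against.

The same pipeline is available from the shell:

```sh
odorforest simulate --seed 7 --molecules 60 --replicated 6 --subjects 6 \
    --attributes 6 --descriptors 60 --out-dir study/
odorforest evaluate --ratings study/ratings.tsv \
    --descriptors study/descriptors.tsv --names study/names.tsv \
    --alpha 0.2 --trees 100 --k 5 --out scores.tsv
odorforest importance --ratings study/ratings.tsv \
    --descriptors study/descriptors.tsv --top-k 5 --out report.tsv
```

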