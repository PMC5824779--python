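"""Per-(subject, attribute) regression model matrix with target blending.

One random forest is trained for every combination of subject and
perceptual attribute — 49 subjects x 21 attributes = 1029 models in the
challenge configuration — plus one population model per attribute.  Each
individual model's target is the convex blend

    y = alpha * y_individual + (1 - alpha) * y_population

where ``y_population`` is the mean rating over subjects for the same
stimulus/provenance and ``alpha`` defaults to 0.2: leaning heavily on the
population signal damps the large rater-to-rater noise while retaining a
personalized component.

Alternative base learners (linear, ridge alpha=10, SVR rbf C=1000
gamma=0.01) are available for comparison; the random forest uses 100 trees
and otherwise library defaults.  Predictions from descriptor-based and
name-fingerprint-based model matrices can be combined by weighted
averaging (the molecular+name ensemble).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.svm import SVR

from .io import POPULATION_SUBJECT, PredictionTensor, ValidationError
from .preprocess import ExampleSet

LEARNER_KINDS = ("random_forest", "linear", "ridge", "svr_rbf")

RATING_MIN = 0.0
RATING_MAX = 100.0


@dataclass
class BlendSpec:
    """Weight of the individual rating in the blended training target."""

    alpha: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass
class LearnerSpec:
    """Base-learner choice and hyperparameters (defaults from the method)."""

    kind: str = "random_forest"
    n_trees: int = 100
    ridge_alpha: float = 10.0
    svr_c: float = 1000.0
    svr_gamma: float = 0.01
    seed: int = 0
    min_examples: int = 5

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"kind must be one of {LEARNER_KINDS}, got {self.kind!r}")


def make_estimator(spec: LearnerSpec, seed: int | None = None):
    """Instantiate the scikit-learn estimator for a learner spec."""
    if spec.kind == "random_forest":
        return RandomForestRegressor(
            n_estimators=spec.n_trees,
            random_state=spec.seed if seed is None else seed,
        )
    if spec.kind == "linear":
        return LinearRegression()
    if spec.kind == "ridge":
        return Ridge(alpha=spec.ridge_alpha)
    return SVR(kernel="rbf", C=spec.svr_c, gamma=spec.svr_gamma)


def model_seed(base_seed: int, subject, attribute: str) -> int:
    """Deterministic per-model seed: base + stable hash of (subject, attribute)."""
    tag = f"{subject}|{attribute}".encode()
    return int((base_seed + zlib.crc32(tag)) % (2**31))


def population_target(values: Sequence[float]) -> float:
    """Mean over non-missing subject ratings; NaN when all are missing."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def population_targets(examples: ExampleSet) -> pd.DataFrame:
    """Population example set: the across-subject mean target per stimulus.

    One row per (attribute, cid, replicate, provenance) with the mean of
    the individual example targets over the subjects that contributed one.
    """
    grouped = (
        examples.data.groupby(["attribute", "cid", "replicate", "provenance"], sort=True)[
            "target"
        ]
        .mean()
        .rename("target")
        .reset_index()
    )
    return grouped


def blend_targets(y_individual, y_population, blend: BlendSpec):
    """``alpha * y_individual + (1 - alpha) * y_population`` (elementwise)."""
    a = blend.alpha
    return a * np.asarray(y_individual, dtype=float) + (1.0 - a) * np.asarray(
        y_population, dtype=float
    )


@dataclass
class ModelMatrix:
    """Trained regressors indexed by (subject, attribute) plus population models."""

    models: dict = field(default_factory=dict)  # (subject, attribute) -> estimator
    population_models: dict = field(default_factory=dict)  # attribute -> estimator
    subjects: tuple = ()
    attributes: tuple[str, ...] = ()
    feature_columns: tuple[str, ...] = ()
    spec: LearnerSpec = field(default_factory=LearnerSpec)
    blend: BlendSpec = field(default_factory=BlendSpec)
    skipped: tuple = ()  # (subject, attribute) pairs with too few examples
    attribute_means: dict = field(default_factory=dict)  # fallback predictions

    @property
    def n_individual_models(self) -> int:
        return len(self.models)


def _feature_rows(features: pd.DataFrame, cids: np.ndarray) -> np.ndarray:
    index = pd.Index(features.index)
    locs = index.get_indexer(cids)
    if (locs < 0).any():
        missing = sorted(set(cids[locs < 0].tolist()))
        raise ValidationError(f"no feature row for cid(s) {missing[:5]}")
    return features.to_numpy(dtype=float)[locs]


def train_model_matrix(
    examples: ExampleSet,
    features: pd.DataFrame,
    spec: LearnerSpec | None = None,
    blend: BlendSpec | None = None,
) -> ModelMatrix:
    """Fit one regressor per (subject, attribute) on blended targets.

    ``features`` is a molecules x features frame indexed by cid (replicates
    share their molecule's row).  A population model per attribute is fitted
    on the pure population targets (alpha = 0).  Pairs with fewer than
    ``spec.min_examples`` examples are skipped with a warning; prediction
    falls back to the population model for them.  Deterministic given
    ``spec.seed``.
    """
    spec = spec or LearnerSpec()
    blend = blend or BlendSpec()
    pop = population_targets(examples)
    data = examples.data.merge(
        pop.rename(columns={"target": "y_population"}),
        on=["attribute", "cid", "replicate", "provenance"],
        how="left",
    )
    data["y_blend"] = blend_targets(data["target"], data["y_population"], blend)

    subjects = tuple(sorted(data["subject"].unique().tolist()))
    attributes = tuple(a for a in examples.attributes if a in set(data["attribute"]))

    mm = ModelMatrix(
        subjects=subjects,
        attributes=attributes,
        feature_columns=tuple(features.columns),
        spec=spec,
        blend=blend,
    )
    fvals = features  # row lookup happens per group

    skipped: list = []
    for (subject, attribute), group in data.groupby(["subject", "attribute"], sort=True):
        if len(group) < spec.min_examples:
            skipped.append((subject, attribute))
            continue
        X = _feature_rows(fvals, group["cid"].to_numpy())
        y = group["y_blend"].to_numpy(dtype=float)
        # seed depends on the attribute only: with alpha = 0 every subject's
        # model shares its targets and must come out identical
        est = make_estimator(spec, seed=model_seed(spec.seed, "model", attribute))
        est.fit(X, y)
        mm.models[(subject, attribute)] = est

    for attribute, group in pop.groupby("attribute", sort=True):
        mm.attribute_means[attribute] = float(group["target"].mean())
        if len(group) < spec.min_examples:
            continue
        X = _feature_rows(fvals, group["cid"].to_numpy())
        y = group["target"].to_numpy(dtype=float)
        est = make_estimator(spec, seed=model_seed(spec.seed, "model", attribute))
        est.fit(X, y)
        mm.population_models[attribute] = est

    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} (subject, attribute) model(s) with fewer than "
            f"{spec.min_examples} examples",
            stacklevel=2,
        )
    mm.skipped = tuple(skipped)
    return mm


def _check_features(mm: ModelMatrix, features: pd.DataFrame) -> np.ndarray:
    if tuple(features.columns) != mm.feature_columns:
        raise ValidationError("feature columns do not match the training signature")
    return features.to_numpy(dtype=float)


def predict_matrix(mm: ModelMatrix, features: pd.DataFrame) -> PredictionTensor:
    """Predict every (cid, subject, attribute); values clipped to [0, 100].

    Skipped (subject, attribute) pairs fall back to the population model,
    then to the training-set attribute mean.
    """
    X = _check_features(mm, features)
    cids = tuple(int(c) for c in features.index)
    values = np.empty((len(cids), len(mm.subjects), len(mm.attributes)), dtype=float)
    pop_cache: dict[str, np.ndarray] = {}
    for j, attribute in enumerate(mm.attributes):
        pop_model = mm.population_models.get(attribute)
        if pop_model is not None:
            pop_cache[attribute] = pop_model.predict(X)
        for i, subject in enumerate(mm.subjects):
            model = mm.models.get((subject, attribute))
            if model is not None:
                values[:, i, j] = model.predict(X)
            elif attribute in pop_cache:
                values[:, i, j] = pop_cache[attribute]
            else:
                values[:, i, j] = mm.attribute_means.get(attribute, 50.0)
    return PredictionTensor(values, cids, mm.subjects, mm.attributes, scope="individual")


def predict_population(
    mm: ModelMatrix, features: pd.DataFrame, mode: str = "population_model"
) -> PredictionTensor:
    """Population-level predictions for every (cid, attribute).

    ``mode="population_model"`` uses the per-attribute model trained on
    population (alpha = 0) targets; ``mode="average_individuals"`` averages
    the predictions of the individual models.
    """
    if mode not in {"population_model", "average_individuals"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "average_individuals":
        individual = predict_matrix(mm, features)
        values = individual.values.mean(axis=1, keepdims=True)
        return PredictionTensor(
            values, individual.cids, (POPULATION_SUBJECT,), mm.attributes, scope="population"
        )
    X = _check_features(mm, features)
    cids = tuple(int(c) for c in features.index)
    values = np.empty((len(cids), 1, len(mm.attributes)), dtype=float)
    for j, attribute in enumerate(mm.attributes):
        model = mm.population_models.get(attribute)
        if model is not None:
            values[:, 0, j] = model.predict(X)
        else:
            values[:, 0, j] = mm.attribute_means.get(attribute, 50.0)
    return PredictionTensor(values, cids, (POPULATION_SUBJECT,), mm.attributes, scope="population")


def ensemble_predict(
    p_molecular: PredictionTensor,
    p_name: PredictionTensor,
    weights: tuple[float, float] = (0.5, 0.5),
) -> PredictionTensor:
    """Weighted average of two prediction tensors over a shared index."""
    for attr in ("cids", "subjects", "attributes", "scope"):
        if getattr(p_molecular, attr) != getattr(p_name, attr):
            raise ValidationError(f"prediction tensors disagree on {attr}")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("ensemble weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("at least one ensemble weight must be positive")
    w = w / total
    values = w[0] * p_molecular.values + w[1] * p_name.values
    return PredictionTensor(
        values, p_molecular.cids, p_molecular.subjects, p_molecular.attributes, p_molecular.scope
    )


def fit_baseline(kind: str, X, y, spec: LearnerSpec | None = None, seed: int | None = None):
    """Fit one baseline learner with the method's default hyperparameters."""
    spec = spec or LearnerSpec()
    if kind not in LEARNER_KINDS:
        raise ValueError(f"kind must be one of {LEARNER_KINDS}, got {kind!r}")
    est = make_estimator(
        LearnerSpec(
            kind=kind,
            n_trees=spec.n_trees,
            ridge_alpha=spec.ridge_alpha,
            svr_c=spec.svr_c,
            svr_gamma=spec.svr_gamma,
            seed=spec.seed,
        ),
        seed=seed,
    )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError(f"feature/target length mismatch: {X.shape[0]} vs {y.shape[0]}")
    est.fit(X, y)
    return est
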