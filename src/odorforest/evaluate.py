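"""Cross-validated evaluation and descriptive variability statistics.

Molecules (not stimuli) are partitioned into k = 5 folds, so both
concentrations and both replicates of a molecule always live on the same
side of the split.  Within each fold the whole pipeline — min-max scaler,
name vocabulary, population targets, model matrix — is fitted on the
training molecules only, the held-out molecules are predicted, and each
attribute is scored with Pearson's correlation between observed and
predicted ratings pooled over (molecule, subject) pairs (per-subject
scoring is available as a flag).

The observed rating an attribute is scored against mirrors its example
definition: the high-concentration rating for semantic attributes and
pleasantness, the configured-dilution rating for intensity.

Inter-individual variability is summarized by the coefficient of
variation: per stimulus, across-subject sd/mean, averaged over stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from . import model as model_mod
from . import name_features as nf
from .io import AlignedData, RatingsTable
from .preprocess import (
    DEFAULT_INTENSITY_DILUTION,
    PROVENANCE_DILUTION,
    PROVENANCE_HIGH,
    apply_scaler,
    build_examples,
    fit_scaler,
)

FEATURE_MODES = ("molecular", "name", "both")


def pearson(x, y) -> float:
    """Pearson correlation after dropping pairs with a missing member.

    Raises on fewer than 2 complete pairs; returns NaN (a MISSING score)
    when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError(f"need at least 2 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CVPlan:
    """Seeded assignment of molecules to folds.

    Replicates share their partner's cid and therefore its fold, so
    ``group_replicates`` is honored by construction.
    """

    assignments: dict[int, int]
    k: int = 5
    seed: int = 0
    group_replicates: bool = True

    def folds(self):
        cids = np.asarray(sorted(self.assignments))
        labels = np.asarray([self.assignments[c] for c in cids])
        for fold in range(self.k):
            yield cids[labels != fold], cids[labels == fold]


def make_cv_plan(
    cids: Iterable[int], k: int = 5, seed: int = 0, group_replicates: bool = True
) -> CVPlan:
    """Random k-fold partition of the molecule set (sizes differ by <= 1)."""
    unique = np.asarray(sorted(set(int(c) for c in cids)))
    if len(unique) < k:
        raise ValueError(f"need at least k={k} distinct cids, got {len(unique)}")
    assignments: dict[int, int] = {}
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(unique)):
        for c in unique[test_idx]:
            assignments[int(c)] = fold
    return CVPlan(assignments, k=k, seed=seed, group_replicates=group_replicates)


@dataclass
class ScoreTable:
    """Per-(attribute, fold) Pearson correlations with aggregation views."""

    data: pd.DataFrame  # columns: attribute, fold, pearson_r

    def mean_by_attribute(self) -> pd.Series:
        return self.data.groupby("attribute", sort=False)["pearson_r"].mean()

    def overall_mean(self) -> float:
        return float(self.mean_by_attribute().mean())


def observed_targets(
    ratings: RatingsTable,
    intensity_dilution: str = DEFAULT_INTENSITY_DILUTION,
) -> pd.DataFrame:
    """Ground-truth ratings to score against, one row per
    (cid, replicate, subject, attribute)."""
    examples = build_examples(ratings, intensity_dilution=intensity_dilution, emit_mean=False)
    d = examples.data
    keep = d["provenance"].isin([PROVENANCE_HIGH, PROVENANCE_DILUTION])
    return d.loc[keep, ["cid", "replicate", "subject", "attribute", "target"]].rename(
        columns={"target": "observed"}
    )


def _fold_predictions(
    dataset: AlignedData,
    train_cids: np.ndarray,
    test_cids: np.ndarray,
    spec: model_mod.LearnerSpec,
    blend: model_mod.BlendSpec,
    feature_mode: str,
    feature_columns: Sequence[str] | None,
    attributes: Sequence[str] | None,
    intensity_dilution: str,
    emit_mean: bool,
    k_gram: int,
    name_mode: str,
    ensemble_weights: tuple[float, float],
):
    ratings_train = dataset.ratings.subset_cids(train_cids)
    if attributes is not None:
        ratings_train = ratings_train.subset_attributes(attributes)
    examples = build_examples(
        ratings_train, intensity_dilution=intensity_dilution, emit_mean=emit_mean
    )

    tensors = []
    if feature_mode in ("molecular", "both"):
        descriptors = dataset.descriptors
        if feature_columns is not None:
            descriptors = descriptors.subset(columns=feature_columns)
        scaler = fit_scaler(descriptors, training_cids=train_cids)
        scaled = apply_scaler(descriptors, scaler)
        mm = model_mod.train_model_matrix(examples, scaled.data, spec=spec, blend=blend)
        tensors.append(model_mod.predict_matrix(mm, scaled.data.loc[list(test_cids)]))
    if feature_mode in ("name", "both"):
        train_names = [dataset.names[int(c)] for c in sorted(int(c) for c in train_cids)]
        vocab = nf.build_vocabulary(train_names, k=k_gram, mode=name_mode)
        fp = nf.fingerprint_matrix(dataset.names, vocab, cids=sorted(dataset.names))
        mm = model_mod.train_model_matrix(examples, fp, spec=spec, blend=blend)
        tensors.append(model_mod.predict_matrix(mm, fp.loc[list(test_cids)]))
    if len(tensors) == 2:
        return model_mod.ensemble_predict(tensors[0], tensors[1], weights=ensemble_weights)
    return tensors[0]


def cross_validate(
    dataset: AlignedData,
    spec: model_mod.LearnerSpec | None = None,
    blend: model_mod.BlendSpec | None = None,
    plan: CVPlan | None = None,
    feature_mode: str = "molecular",
    feature_columns: Sequence[str] | None = None,
    attributes: Sequence[str] | None = None,
    per_subject: bool = False,
    intensity_dilution: str = DEFAULT_INTENSITY_DILUTION,
    emit_mean: bool = True,
    k_gram: int = nf.DEFAULT_WINDOW,
    name_mode: str = "strict",
    ensemble_weights: tuple[float, float] = (0.5, 0.5),
) -> ScoreTable:
    """k-fold cross-validation of the full pipeline, scored per attribute.

    Every fold refits scaler, vocabulary, population targets, and models on
    its training molecules only.  Degenerate folds (constant observations
    or fewer than 2 scored pairs) get a NaN score with a warning.
    """
    if feature_mode not in FEATURE_MODES:
        raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
    spec = spec or model_mod.LearnerSpec()
    blend = blend or model_mod.BlendSpec()
    if plan is None:
        plan = make_cv_plan(dataset.cids, k=5, seed=spec.seed)

    observed = observed_targets(dataset.ratings, intensity_dilution=intensity_dilution)
    if attributes is not None:
        observed = observed[observed["attribute"].isin(set(attributes))]
    scored_attrs = (
        tuple(attributes)
        if attributes is not None
        else tuple(a for a in dataset.ratings.attributes if a in set(observed["attribute"]))
    )

    rows = []
    for fold, (train_cids, test_cids) in enumerate(plan.folds()):
        tensor = _fold_predictions(
            dataset,
            train_cids,
            test_cids,
            spec,
            blend,
            feature_mode,
            feature_columns,
            attributes,
            intensity_dilution,
            emit_mean,
            k_gram,
            name_mode,
            ensemble_weights,
        )
        pred = tensor.to_frame().rename(columns={"value": "predicted"})
        fold_obs = observed[observed["cid"].isin(set(int(c) for c in test_cids))]
        merged = fold_obs.merge(pred, on=["cid", "subject", "attribute"], how="inner")
        for attribute in scored_attrs:
            sub = merged[merged["attribute"] == attribute]
            r = _score_group(sub, per_subject)
            if np.isnan(r):
                warnings.warn(
                    f"degenerate fold {fold} for attribute {attribute!r}: score is missing",
                    stacklevel=2,
                )
            rows.append({"attribute": attribute, "fold": fold, "pearson_r": r})
    return ScoreTable(pd.DataFrame(rows))


def _score_group(sub: pd.DataFrame, per_subject: bool) -> float:
    def safe_pearson(obs, pred) -> float:
        if len(obs) < 2:
            return float("nan")
        return pearson(obs, pred)

    if not per_subject:
        return safe_pearson(sub["observed"].to_numpy(), sub["predicted"].to_numpy())
    scores = [
        safe_pearson(g["observed"].to_numpy(), g["predicted"].to_numpy())
        for _, g in sub.groupby("subject")
    ]
    scores = [s for s in scores if not np.isnan(s)]
    return float(np.mean(scores)) if scores else float("nan")


def coefficient_of_variation(ratings: RatingsTable, attribute: str) -> float:
    """Across-subject sd/mean per stimulus, averaged over stimuli.

    Sample (n-1) standard deviation; stimuli with mean 0 or fewer than 2
    non-missing ratings are excluded; NaN when nothing qualifies.
    """
    if attribute not in ratings.attributes:
        raise ValueError(f"unknown attribute {attribute!r}")
    d = ratings.data
    d = d[(d["attribute"] == attribute) & d["value"].notna()]
    if d.empty:
        return float("nan")
    grouped = d.groupby(["cid", "replicate", "concentration"])["value"]
    stats_ = grouped.agg(["mean", "std", "count"])
    ok = (stats_["count"] >= 2) & (stats_["mean"] > 0)
    if not ok.any():
        return float("nan")
    cv = stats_.loc[ok, "std"] / stats_.loc[ok, "mean"]
    return float(cv.mean())
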