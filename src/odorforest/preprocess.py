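"""Dataset preprocessing: missingness, example construction, feature scaling.

The training examples for each (subject, attribute) regressor are derived
from the raw panel as follows:

* records with a missing rating are dropped (in the study, an odorless
  stimulus received intensity 0 and blanks elsewhere — the intensity-0
  record survives, the blanks do not);
* intensity examples come from the presentations at the "1/1000" dilution;
* every other attribute contributes one example from the high-concentration
  rating and — when both concentrations were rated — a second example equal
  to the mean of the high and low ratings, which doubles the sample size;
* replicated molecules stay as separate examples throughout.

Descriptors are min-max scaled to [0, 1] column-wise with statistics fitted
on training molecules only: ``x' = (x - min(x)) / (max(x) - min(x))``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    CONCENTRATION_HIGH,
    CONCENTRATION_LOW,
    DescriptorMatrix,
    RatingsTable,
    ValidationError,
)

#: Provenance tags recorded per training example.
PROVENANCE_HIGH = "high"
PROVENANCE_MEAN = "mean_high_low"
PROVENANCE_DILUTION = "dilution_1_1000"

DEFAULT_INTENSITY_DILUTION = "1/1,000"

EXAMPLE_COLUMNS = ("subject", "attribute", "cid", "replicate", "provenance", "target")


class ScalingError(ValueError):
    """A descriptor column cannot be scaled (e.g. no observed value)."""


@dataclass
class ExampleSet:
    """Per-(subject, attribute) training examples with provenance tags.

    ``data`` columns: subject, attribute, cid, replicate, provenance,
    target.  Targets are never missing; replicates appear as separate rows.
    """

    data: pd.DataFrame
    attributes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.attributes = tuple(self.attributes)
        if self.data["target"].isna().any():
            raise ValidationError("example targets must not be missing")

    def for_model(self, subject: int, attribute: str) -> pd.DataFrame:
        d = self.data
        return d[(d["subject"] == subject) & (d["attribute"] == attribute)]

    def __len__(self) -> int:
        return len(self.data)


def drop_missing(ratings: RatingsTable) -> RatingsTable:
    """Remove records whose rating is missing; intensity-0 records stay."""
    keep = ratings.data["value"].notna()
    return RatingsTable(ratings.data.loc[keep].reset_index(drop=True), ratings.attributes)


def normalize_dilution(label: str) -> str:
    """Canonicalize a dilution string: ``"1/1,000"`` == ``"1/1000"``."""
    return re.sub(r"[,\s]", "", str(label)).lower()


def select_intensity_targets(
    ratings: RatingsTable,
    dilution_label: str = DEFAULT_INTENSITY_DILUTION,
) -> pd.DataFrame:
    """Intensity examples: ratings at the configured dilution only.

    Matching is exact after normalization (commas/spaces stripped).  When
    the table carries no dilution strings, the label is matched against the
    concentration column instead, so ``"low"`` selects the low presentations.
    Returns an example-set slice (may be empty, with a warning).
    """
    df = ratings.data
    df = df[(df["attribute"] == "intensity") & df["value"].notna()]
    want = normalize_dilution(dilution_label)
    has_dilution = df["dilution"].astype(str).str.strip().ne("").any()
    if has_dilution:
        match = df["dilution"].map(normalize_dilution) == want
    else:
        match = df["concentration"].astype(str).str.strip().str.lower() == want
    out = df.loc[match, ["subject", "cid", "replicate", "value"]].copy()
    if out.empty:
        warnings.warn(
            f"no intensity record matches dilution {dilution_label!r}; "
            "intensity models will have no examples",
            stacklevel=2,
        )
    out["attribute"] = "intensity"
    out["provenance"] = PROVENANCE_DILUTION
    out = out.rename(columns={"value": "target"})
    return out[list(EXAMPLE_COLUMNS)].reset_index(drop=True)


def _semantic_examples(ratings: RatingsTable, emit_mean: bool = True) -> pd.DataFrame:
    """High-concentration + high/low-mean examples for non-intensity attributes."""
    df = ratings.data
    df = df[df["attribute"] != "intensity"]
    pivot = df.pivot_table(
        index=["subject", "attribute", "cid", "replicate"],
        columns="concentration",
        values="value",
        aggfunc="first",
        dropna=False,
    )
    high = pivot.get(CONCENTRATION_HIGH)
    if high is None:
        return pd.DataFrame(columns=list(EXAMPLE_COLUMNS))
    low = pivot.get(CONCENTRATION_LOW)

    frames = []
    h = high.dropna()
    h_frame = h.reset_index().rename(columns={CONCENTRATION_HIGH: "target"})
    h_frame["provenance"] = PROVENANCE_HIGH
    frames.append(h_frame)
    if emit_mean and low is not None:
        both = pd.concat([high, low], axis=1).dropna()
        if len(both):
            m_frame = both.mean(axis=1).rename("target").reset_index()
            m_frame["provenance"] = PROVENANCE_MEAN
            frames.append(m_frame)
    out = pd.concat(frames, ignore_index=True)
    return out[list(EXAMPLE_COLUMNS)]


def build_attribute_examples(
    ratings: RatingsTable, attribute: str, emit_mean: bool = True
) -> pd.DataFrame:
    """Example slice for one non-intensity attribute.

    Each stimulus yields the high-concentration rating as one example and,
    when both concentrations are rated, the high/low mean as a second one
    (sample-size doubling).  A stimulus with only the low rating yields
    nothing — no target is fabricated.
    """
    if attribute == "intensity":
        raise ValueError("intensity examples come from select_intensity_targets")
    if attribute not in ratings.attributes:
        raise ValidationError(f"unknown attribute {attribute!r}")
    sub = ratings.subset_attributes([a for a in ratings.attributes if a == attribute])
    return _semantic_examples(sub, emit_mean=emit_mean)


def build_examples(
    ratings: RatingsTable,
    intensity_dilution: str = DEFAULT_INTENSITY_DILUTION,
    emit_mean: bool = True,
) -> ExampleSet:
    """Full example set across all attributes of the table."""
    frames = [_semantic_examples(ratings, emit_mean=emit_mean)]
    if "intensity" in ratings.attributes:
        frames.insert(0, select_intensity_targets(ratings, intensity_dilution))
    data = pd.concat([f for f in frames if len(f)], ignore_index=True)
    if data.empty:
        data = pd.DataFrame(columns=list(EXAMPLE_COLUMNS))
    data = data.astype({"subject": np.int64, "cid": np.int64, "replicate": np.int64})
    data = data.sort_values(["attribute", "subject", "cid", "replicate", "provenance"]).reset_index(
        drop=True
    )
    return ExampleSet(data, ratings.attributes)


# ---------------------------------------------------------------------------
# Min-max scaling


@dataclass
class ScalerState:
    """Per-column (min, max) fitted on training molecules, plus the
    training median used to impute missing descriptor cells."""

    columns: tuple[str, ...]
    col_min: np.ndarray
    col_max: np.ndarray
    col_median: np.ndarray

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        if np.any(self.col_max < self.col_min):
            raise ScalingError("max < min in scaler state")


def fit_scaler(d: DescriptorMatrix, training_cids=None) -> ScalerState:
    """Fit column extrema (and imputation medians) on training rows only."""
    sub = d if training_cids is None else d.subset(cids=training_cids)
    values = sub.data.to_numpy(dtype=float)
    all_missing = np.isnan(values).all(axis=0)
    if all_missing.any():
        bad = [sub.data.columns[i] for i in np.flatnonzero(all_missing)]
        raise ScalingError(f"column(s) with no observed training value: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ScalerState(
            columns=tuple(sub.data.columns),
            col_min=np.nanmin(values, axis=0),
            col_max=np.nanmax(values, axis=0),
            col_median=np.nanmedian(values, axis=0),
        )


def apply_scaler(d: DescriptorMatrix, s: ScalerState) -> DescriptorMatrix:
    """Scale every column with the training extrema.

    Missing cells are imputed with the training median first.  Constant
    columns map to 0.  Values outside the training range are *not*
    clipped, so test rows may fall outside [0, 1]; training rows by
    construction land inside it.
    """
    if tuple(d.data.columns) != s.columns:
        unknown = set(d.data.columns) - set(s.columns)
        raise ScalingError(
            f"descriptor columns do not match scaler columns "
            f"(e.g. {sorted(unknown)[:3] if unknown else list(s.columns)[:3]})"
        )
    values = d.data.to_numpy(dtype=float, copy=True)
    nan_mask = np.isnan(values)
    if nan_mask.any():
        values[nan_mask] = np.broadcast_to(s.col_median, values.shape)[nan_mask]
    span = s.col_max - s.col_min
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = (values - s.col_min) / safe_span
    scaled[:, constant] = 0.0
    out = pd.DataFrame(scaled, index=d.data.index, columns=d.data.columns)
    return DescriptorMatrix(
        out,
        scaling_state="unit_scaled",
        col_min=pd.Series(s.col_min, index=list(s.columns)),
        col_max=pd.Series(s.col_max, index=list(s.columns)),
    )


def inverse_scale(d: DescriptorMatrix, s: ScalerState) -> DescriptorMatrix:
    """Undo :func:`apply_scaler`: ``x = x' * (max - min) + min``.

    Constant columns are restored to their constant training value.
    """
    if tuple(d.data.columns) != s.columns:
        raise ScalingError("descriptor columns do not match scaler columns")
    span = s.col_max - s.col_min
    values = d.data.to_numpy(dtype=float) * span + s.col_min
    constant = span == 0
    values[:, constant] = s.col_min[constant]
    return DescriptorMatrix(pd.DataFrame(values, index=d.data.index, columns=d.data.columns))
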