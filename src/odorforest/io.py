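"""Data containers and tabular I/O for the olfaction-prediction pipeline.

The pipeline consumes three tables:

* a long psychophysical **ratings** panel — one stimulus presentation per
  row (molecule CID, replicate flag, high/low concentration label, dilution
  string, subject id) with one column per perceptual attribute on the 0-100
  rating scale;
* a molecules x descriptors numeric matrix (Dragon-style chemoinformatic
  features, one row per CID);
* a CID -> chemical-name map used to build name fingerprints.

All files are tab-separated UTF-8 with a header row; ``NA`` (or an empty
cell) marks a missing value.  A best-effort ``challenge`` dialect maps the
column layout of the published DREAM olfaction challenge files onto the
canonical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The 21 perceptual attributes of the challenge panel: odor intensity,
#: pleasantness, and 19 semantic descriptors.  Intensity is always first —
#: it is the one attribute with its own preprocessing path.
CANONICAL_ATTRIBUTES: tuple[str, ...] = (
    "intensity",
    "pleasantness",
    "bakery",
    "sweet",
    "fruit",
    "fish",
    "garlic",
    "spices",
    "cold",
    "sour",
    "burnt",
    "acid",
    "warm",
    "musky",
    "sweaty",
    "ammonia/urinous",
    "decayed",
    "wood",
    "grass",
    "flower",
    "chemical",
)

#: Structure of the DREAM challenge dataset (used for defaults and for the
#: replicate-fraction bookkeeping of the combined training set).
CHALLENGE_TRAINING_MOLECULES = 338
CHALLENGE_LEADERBOARD_MOLECULES = 69
CHALLENGE_TEST_MOLECULES = 69
CHALLENGE_REPLICATED_MOLECULES = 20
CHALLENGE_SUBJECTS = 49

MISSING_TOKEN = "NA"
META_COLUMNS = ("cid", "replicate", "concentration", "dilution", "subject")

CONCENTRATION_HIGH = "high"
CONCENTRATION_LOW = "low"


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant (range, duplicates...)."""


class AlignmentError(ValueError):
    """No molecule survives the intersection of the input sources."""


def replicate_training_fraction(
    n_replicated: int = CHALLENGE_REPLICATED_MOLECULES,
    n_training: int = CHALLENGE_TRAINING_MOLECULES + CHALLENGE_LEADERBOARD_MOLECULES,
) -> float:
    """Fraction of replicated molecules in a training-set configuration.

    For the challenge's combined training set (338 training + 69
    leaderboard molecules, 20 of them replicated) this is 20/407 = 0.049.
    """
    if n_training <= 0:
        raise ValueError("n_training must be positive")
    return n_replicated / n_training


# ---------------------------------------------------------------------------
# Ratings


@dataclass
class RatingsTable:
    """Long-form psychophysical ratings.

    ``data`` has one row per (cid, replicate, concentration, subject,
    attribute) with a float ``value`` in [0, 100] or NaN for missing.
    ``dilution`` is a free-form dilution string (may be empty).
    """

    data: pd.DataFrame
    attributes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.attributes = tuple(self.attributes)

    # -- derived views ----------------------------------------------------

    @property
    def cids(self) -> np.ndarray:
        return np.sort(self.data["cid"].unique())

    @property
    def subjects(self) -> np.ndarray:
        return np.sort(self.data["subject"].unique())

    @property
    def n_missing(self) -> int:
        return int(self.data["value"].isna().sum())

    def subset_cids(self, cids: Iterable[int]) -> "RatingsTable":
        keep = self.data["cid"].isin(set(int(c) for c in cids))
        return RatingsTable(self.data.loc[keep].reset_index(drop=True), self.attributes)

    def subset_attributes(self, attributes: Iterable[str]) -> "RatingsTable":
        attrs = tuple(attributes)
        unknown = set(attrs) - set(self.attributes)
        if unknown:
            raise ValidationError(f"unknown attributes: {sorted(unknown)}")
        keep = self.data["attribute"].isin(attrs)
        return RatingsTable(self.data.loc[keep].reset_index(drop=True), attrs)

    def to_wide(self) -> pd.DataFrame:
        """One row per stimulus presentation, one column per attribute."""
        wide = (
            self.data.set_index(list(META_COLUMNS) + ["attribute"])["value"]
            .unstack("attribute")
            .reindex(columns=list(self.attributes))
            .reset_index()
        )
        wide.columns.name = None
        return wide.sort_values(["cid", "replicate", "concentration", "subject"]).reset_index(
            drop=True
        )

    # -- invariants --------------------------------------------------------

    def validate(self) -> "RatingsTable":
        df = self.data
        required = set(META_COLUMNS) | {"attribute", "value"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"ratings table lacks columns: {sorted(missing)}")
        if len(self.attributes) == 0:
            raise ValidationError("no perceptual attributes defined")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValidationError("attribute names must be unique")
        if "intensity" in self.attributes and self.attributes[0] != "intensity":
            raise ValidationError("'intensity' must be the first attribute")
        unknown = set(df["attribute"].unique()) - set(self.attributes)
        if unknown:
            raise ValidationError(f"records reference unknown attributes: {sorted(unknown)}")

        values = df["value"].to_numpy(dtype=float)
        bad = (~np.isnan(values)) & ((values < 0.0) | (values > 100.0))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            row = df.iloc[i]
            raise ValidationError(
                f"rating {row['value']!r} outside [0, 100] at cid={row['cid']} "
                f"replicate={row['replicate']} concentration={row['concentration']} "
                f"subject={row['subject']} attribute={row['attribute']}"
            )

        keys = ["cid", "replicate", "concentration", "subject", "attribute"]
        if df.duplicated(subset=keys).any():
            dup = df[df.duplicated(subset=keys, keep=False)].iloc[0]
            raise ValidationError(
                f"duplicate record for cid={dup['cid']} replicate={dup['replicate']} "
                f"concentration={dup['concentration']} subject={dup['subject']} "
                f"attribute={dup['attribute']}"
            )

        subjects = self.subjects
        if len(subjects) and not np.array_equal(subjects, np.arange(1, len(subjects) + 1)):
            raise ValidationError(
                f"subject ids must form a contiguous 1..S set, got {subjects.tolist()[:10]}..."
            )
        if (df["cid"].to_numpy() <= 0).any():
            raise ValidationError("cids must be positive integers")
        if not df["replicate"].isin([0, 1]).all():
            raise ValidationError("replicate index must be 0 or 1")
        return self


_CHALLENGE_META = {
    "compound identifier": "cid",
    "odor": "name",
    "replicate": "replicate",
    "intensity": "concentration",
    "dilution": "dilution",
    "subject #": "subject",
    "subject": "subject",
}
_CHALLENGE_ATTRIBUTES = {
    "intensity/strength": "intensity",
    "valence/pleasantness": "pleasantness",
}


def _challenge_to_canonical(raw: pd.DataFrame) -> pd.DataFrame:
    """Best-effort mapping of the published challenge layout to canonical."""
    renames: dict[str, str] = {}
    for col in raw.columns:
        key = str(col).strip().lower()
        if key in _CHALLENGE_META:
            renames[col] = _CHALLENGE_META[key]
        elif key in _CHALLENGE_ATTRIBUTES:
            renames[col] = _CHALLENGE_ATTRIBUTES[key]
        elif key in {a.lower() for a in CANONICAL_ATTRIBUTES}:
            renames[col] = key
    df = raw.rename(columns=renames)
    if "concentration" in df.columns:
        df["concentration"] = df["concentration"].astype(str).str.strip().str.lower()
    if "replicate" in df.columns:
        rep = df["replicate"].astype(str).str.strip().str.lower()
        df["replicate"] = np.where(rep.isin({"", "nan", "0", MISSING_TOKEN.lower()}), 0, 1)
    else:
        df["replicate"] = 0
    if "dilution" not in df.columns:
        df["dilution"] = ""
    df = df.drop(columns=[c for c in ("name",) if c in df.columns])
    return df


def read_ratings(path: str | Path, dialect: str = "canonical") -> RatingsTable:
    """Load a ratings file and validate it.

    ``dialect='canonical'`` expects the wide TSV written by
    :func:`write_ratings`; ``dialect='challenge'`` maps the published
    challenge column names first.  Empty cells and ``NA`` become missing.
    """
    if dialect not in {"canonical", "challenge"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN, ""], keep_default_na=False, dtype=str
    )
    if dialect == "challenge":
        raw = _challenge_to_canonical(raw)

    for col in ("cid", "replicate", "concentration", "subject"):
        if col not in raw.columns:
            raise FormatError(f"ratings file {path} is missing required column {col!r}")
    if "dilution" not in raw.columns:
        raw["dilution"] = ""

    attributes = tuple(c for c in raw.columns if c not in META_COLUMNS)
    if not attributes:
        raise FormatError(f"ratings file {path} has no attribute columns")

    meta = pd.DataFrame(
        {
            "cid": pd.to_numeric(raw["cid"], errors="raise").astype(np.int64),
            "replicate": pd.to_numeric(raw["replicate"], errors="raise").astype(np.int64),
            "concentration": raw["concentration"].astype(str),
            "dilution": raw["dilution"].fillna("").astype(str),
            "subject": pd.to_numeric(raw["subject"], errors="raise").astype(np.int64),
        }
    )
    values = np.empty((len(raw), len(attributes)), dtype=float)
    for j, attr in enumerate(attributes):
        try:
            values[:, j] = pd.to_numeric(raw[attr], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric rating in column {attr!r} of {path}: {exc}") from exc

    long = meta.loc[meta.index.repeat(len(attributes))].reset_index(drop=True)
    long["attribute"] = np.tile(np.asarray(attributes, dtype=object), len(raw))
    long["value"] = values.ravel()
    table = RatingsTable(long, attributes)
    return table.validate()


def write_ratings(table: RatingsTable, path: str | Path) -> Path:
    """Write the canonical wide TSV (``NA`` for missing)."""
    path = Path(path)
    wide = table.to_wide()
    wide.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)
    return path


# ---------------------------------------------------------------------------
# Descriptors


@dataclass
class DescriptorMatrix:
    """Molecules x named numeric chemoinformatic features.

    ``scaling_state`` is ``"raw"`` as loaded, or ``"unit_scaled"`` after
    min-max scaling, in which case the per-column training (min, max) used
    for the transform are stored so test rows reuse training statistics.
    """

    data: pd.DataFrame  # index: cid, columns: descriptor names
    scaling_state: str = "raw"
    col_min: pd.Series | None = None
    col_max: pd.Series | None = None

    @property
    def cids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def subset(
        self,
        cids: Iterable[int] | None = None,
        columns: Iterable[str] | None = None,
    ) -> "DescriptorMatrix":
        df = self.data
        if cids is not None:
            cids = [int(c) for c in cids]
            missing = set(cids) - set(df.index)
            if missing:
                raise KeyError(f"cids absent from descriptor matrix: {sorted(missing)[:5]}")
            df = df.loc[cids]
        if columns is not None:
            columns = list(columns)
            unknown = set(columns) - set(df.columns)
            if unknown:
                raise KeyError(f"unknown descriptor columns: {sorted(unknown)[:5]}")
            df = df[columns]
        sub = DescriptorMatrix(df.copy(), self.scaling_state)
        if self.col_min is not None:
            sub.col_min = self.col_min.loc[list(df.columns)]
            sub.col_max = self.col_max.loc[list(df.columns)]
        return sub


def read_descriptors(path: str | Path) -> DescriptorMatrix:
    """Load a molecules x descriptors TSV (first column = cid)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    names = header[1:]
    dupes = pd.Index(names)[pd.Index(names).duplicated()].unique()
    if len(dupes):
        raise FormatError(f"duplicate descriptor column(s) in {path}: {list(dupes)}")
    raw = pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN, ""], keep_default_na=False, dtype=str
    )
    cid_col = raw.columns[0]
    cids = pd.to_numeric(raw[cid_col], errors="raise").astype(np.int64)
    if cids.duplicated().any():
        raise FormatError(f"duplicate cid rows in {path}")
    values = pd.DataFrame(index=pd.Index(cids, name="cid"))
    for col in raw.columns[1:]:
        try:
            values[col] = pd.to_numeric(raw[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric descriptor value in column {col!r} of {path}: {exc}") from exc
    return DescriptorMatrix(values)


def write_descriptors(d: DescriptorMatrix, path: str | Path) -> Path:
    path = Path(path)
    d.data.to_csv(path, sep="\t", index_label="cid", na_rep=MISSING_TOKEN)
    return path


# ---------------------------------------------------------------------------
# Names


def read_names(path: str | Path) -> dict[int, str]:
    """Load a two-column cid<TAB>name map."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"name map {path} needs two columns (cid, name)")
    cids = pd.to_numeric(raw.iloc[:, 0], errors="raise").astype(np.int64)
    if cids.duplicated().any():
        raise FormatError(f"duplicate cid in name map {path}")
    return dict(zip(cids.tolist(), raw.iloc[:, 1].astype(str).tolist()))


def write_names(names: Mapping[int, str], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"cid": sorted(names), "name": [names[c] for c in sorted(names)]}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Predictions

POPULATION_SUBJECT = "population"


@dataclass
class PredictionTensor:
    """Predicted ratings indexed by (cid, subject, attribute).

    ``scope`` is ``"individual"`` (one layer per subject) or
    ``"population"`` (a single pseudo-subject).  Values are clipped to the
    0-100 rating scale at construction.
    """

    values: np.ndarray
    cids: tuple[int, ...]
    subjects: tuple
    attributes: tuple[str, ...]
    scope: str = "individual"

    def __post_init__(self) -> None:
        self.cids = tuple(int(c) for c in self.cids)
        self.subjects = tuple(self.subjects)
        self.attributes = tuple(self.attributes)
        self.values = np.clip(np.asarray(self.values, dtype=float), 0.0, 100.0)
        expected = (len(self.cids), len(self.subjects), len(self.attributes))
        if self.values.shape != expected:
            raise ValidationError(
                f"prediction tensor shape {self.values.shape} != {expected}"
            )
        if self.scope not in {"individual", "population"}:
            raise ValidationError(f"unknown scope {self.scope!r}")
        if self.scope == "population" and len(self.subjects) != 1:
            raise ValidationError("population tensor must have a single pseudo-subject")

    def to_frame(self) -> pd.DataFrame:
        nc, ns, na = self.values.shape
        return pd.DataFrame(
            {
                "cid": np.repeat(self.cids, ns * na),
                "subject": np.tile(np.repeat(np.asarray(self.subjects, dtype=object), na), nc),
                "attribute": np.tile(np.asarray(self.attributes, dtype=object), nc * ns),
                "value": self.values.ravel(),
            }
        )


def write_predictions(t: PredictionTensor, path: str | Path) -> Path:
    """Long TSV (cid, subject, attribute, value) sorted by cid then subject."""
    path = Path(path)
    df = t.to_frame()
    # rows are already in (cid, subject, attribute-order) order by construction
    df.to_csv(path, sep="\t", index=False)
    return path


def read_predictions(path: str | Path) -> PredictionTensor:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"cid": np.int64, "value": float})
    cids = tuple(sorted(df["cid"].unique()))
    raw_subjects = df["subject"].unique().tolist()
    if all(str(s) == POPULATION_SUBJECT for s in raw_subjects):
        subjects: tuple = (POPULATION_SUBJECT,)
        scope = "population"
    else:
        subjects = tuple(sorted(int(s) for s in raw_subjects))
        df["subject"] = df["subject"].astype(np.int64)
        scope = "individual"
    attributes = tuple(pd.unique(df["attribute"]))
    sub_index = {s: i for i, s in enumerate(subjects)}
    cid_index = {c: i for i, c in enumerate(cids)}
    attr_index = {a: i for i, a in enumerate(attributes)}
    values = np.full((len(cids), len(subjects), len(attributes)), np.nan)
    ci = df["cid"].map(cid_index).to_numpy()
    si = df["subject"].map(sub_index).to_numpy()
    ai = df["attribute"].map(attr_index).to_numpy()
    values[ci, si, ai] = df["value"].to_numpy()
    if np.isnan(values).any():
        raise FormatError(f"prediction file {path} does not cover the full tensor")
    return PredictionTensor(values, cids, subjects, attributes, scope)


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class AlignedData:
    """Ratings, descriptors and names restricted to their common molecules."""

    ratings: RatingsTable
    descriptors: DescriptorMatrix
    names: dict[int, str]
    dropped: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def cids(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.descriptors.cids)


def align(
    ratings: RatingsTable,
    descriptors: DescriptorMatrix,
    names: Mapping[int, str],
) -> AlignedData:
    """Intersect the molecule sets of the three sources.

    Returns the aligned dataset in ascending-cid order together with a
    report of the cids dropped from each source.  Raises
    :class:`AlignmentError` when no molecule is shared.
    """
    r_cids = set(int(c) for c in ratings.cids)
    d_cids = set(int(c) for c in descriptors.cids)
    n_cids = set(int(c) for c in names)
    common = sorted(r_cids & d_cids & n_cids)
    if not common:
        raise AlignmentError("no cid is present in all of ratings, descriptors, and names")
    dropped = {
        "ratings": tuple(sorted(r_cids - set(common))),
        "descriptors": tuple(sorted(d_cids - set(common))),
        "names": tuple(sorted(n_cids - set(common))),
    }
    return AlignedData(
        ratings=ratings.subset_cids(common),
        descriptors=descriptors.subset(cids=common),
        names={c: str(names[c]) for c in common},
        dropped=dropped,
    )
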