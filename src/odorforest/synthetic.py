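"""Seeded generator of synthetic descriptor tables and rating panels.

The generator emulates the structure of the challenge dataset so that the
whole pipeline is exercised without any download: 476 molecules (20 of
them replicated) rated by 49 untrained subjects at two concentrations on
21 attributes, with the behaviors the method has to cope with —

* a planted, sparse, nonlinear structure-percept map: each attribute's
  latent percept is a logistic squashing of a signed weighted sum of 5
  informative descriptors plus one pairwise interaction, so a forest has
  something a linear model cannot fully capture;
* rater-bias archetypes: uniform raters, "high-saturators" who pile
  ratings near 100, and mid-centered raters who compress toward 50, plus
  independent per-rating noise;
* odorless stimuli whose intensity is recorded as exactly 0 with every
  other attribute left missing;
* a fraction of molecules whose intensity rating *decreases* at the high
  concentration (monotonicity violations seen in untrained panels);
* synthetic chemical names that embed attribute-tagged 4-letter tokens,
  so name-window fingerprints carry real signal for semantic attributes.

Everything — values, archetype assignment, missingness, names — is a
deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    CANONICAL_ATTRIBUTES,
    CONCENTRATION_HIGH,
    CONCENTRATION_LOW,
    DescriptorMatrix,
    RatingsTable,
)

ARCHETYPES = ("uniform", "high_saturator", "mid_centered")

#: Dilution strings attached to the two presentations; intensity examples
#: are taken at the low presentation's "1/1,000" dilution.
HIGH_DILUTION = "1/10"
LOW_DILUTION = "1/1,000"

_SYLLABLES = (
    "meth", "eth", "prop", "but", "pent", "hex", "oct", "benz", "phen",
    "cyclo", "iso", "thio", "oxa", "amin", "vinyl", "allyl",
)
_SUFFIXES = ("ol", "al", "one", "ate", "ene", "ine", "thiol", "ether", "acid", "ester")


@dataclass
class PanelConfig:
    """Dimensions and noise structure of a synthetic study panel.

    Defaults are the challenge dataset's dimensions; ``seed`` is mandatory.
    """

    seed: int
    n_molecules: int = 476
    n_replicated: int = 20
    n_subjects: int = 49
    n_attributes: int = 21
    n_descriptors: int = 500
    n_informative: int = 5
    archetype_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    noise_sd: float = 25.0
    odorless_fraction: float = 0.10
    violation_fraction: float = 0.15
    name_signal: bool = True

    def __post_init__(self) -> None:
        for name in ("n_molecules", "n_subjects", "n_attributes", "n_descriptors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_replicated < 0 or self.n_replicated > self.n_molecules:
            raise ValueError("n_replicated must be in [0, n_molecules]")
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative cannot exceed n_descriptors")
        if self.n_attributes * self.n_informative > self.n_descriptors:
            raise ValueError(
                "need n_attributes * n_informative <= n_descriptors for disjoint planting"
            )
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9 or min(self.archetype_mix) < 0:
            raise ValueError("archetype_mix must be non-negative and sum to 1")
        for name in ("odorless_fraction", "violation_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def attributes(self) -> tuple[str, ...]:
        if self.n_attributes <= len(CANONICAL_ATTRIBUTES):
            return CANONICAL_ATTRIBUTES[: self.n_attributes]
        extra = tuple(
            f"attr{i}" for i in range(len(CANONICAL_ATTRIBUTES), self.n_attributes)
        )
        return CANONICAL_ATTRIBUTES + extra

    @property
    def cids(self) -> np.ndarray:
        return np.arange(101, 101 + self.n_molecules, dtype=np.int64)


def _rngs(cfg: PanelConfig) -> tuple[np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


_BLOCK_PREFIXES = ("ATS", "Mor", "P_VSA")  # informative blocks, Dragon-flavored


def generate_descriptors(cfg: PanelConfig) -> tuple[DescriptorMatrix, dict]:
    """Descriptor matrix with planted ground truth.

    Columns mix continuous informative features (disjoint blocks of
    ``n_informative`` per attribute), continuous pure-noise features, and
    low-cardinality "degenerate" integer features (at most 10 distinct
    values, mimicking weakly discriminative atom-count style descriptors).
    Columns arrive in shuffled order and on heterogeneous raw scales.

    The returned truth map records, per attribute, the informative feature
    names, their signed weights, the interacting pair, and the logistic
    shift — everything needed to reconstruct the latent percepts.
    """
    rng, _ = _rngs(cfg)
    n_mol = cfg.n_molecules
    attrs = cfg.attributes
    n_inf_total = cfg.n_attributes * cfg.n_informative
    n_rest = cfg.n_descriptors - n_inf_total
    n_degenerate = int(round(0.4 * n_rest))
    n_noise = n_rest - n_degenerate

    inf_names = [
        f"{_BLOCK_PREFIXES[i % len(_BLOCK_PREFIXES)]}{i:03d}s" for i in range(n_inf_total)
    ]
    noise_names = [f"Eig{i:03d}v" for i in range(n_noise)]
    degen_names = [f"nX{i:03d}" for i in range(n_degenerate)]

    inf_scale = rng.uniform(0.5, 30.0, n_inf_total)
    inf_offset = rng.uniform(-10.0, 50.0, n_inf_total)
    inf_values = rng.normal(size=(n_mol, n_inf_total)) * inf_scale + inf_offset
    noise_values = (
        rng.normal(size=(n_mol, n_noise)) * rng.uniform(0.5, 30.0, n_noise)
        + rng.uniform(-10.0, 50.0, n_noise)
    )
    degen_values = rng.integers(0, 6, size=(n_mol, n_degenerate)).astype(float)

    frame = pd.DataFrame(
        np.hstack([inf_values, noise_values, degen_values]),
        index=pd.Index(cfg.cids, name="cid"),
        columns=inf_names + noise_names + degen_names,
    )
    order = rng.permutation(frame.shape[1])
    frame = frame.iloc[:, order]

    truth: dict = {
        "attributes": list(attrs),
        "informative": {},
        "weights": {},
        "interaction_pair": {},
        "interaction_weight": 0.6,
        "logistic_slope": 1.3,
        "logistic_shift": {},
    }
    for a_idx, attribute in enumerate(attrs):
        cols = inf_names[a_idx * cfg.n_informative : (a_idx + 1) * cfg.n_informative]
        signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
        w = signs * rng.uniform(0.5, 1.0, cfg.n_informative)
        w = w / np.linalg.norm(w)
        truth["informative"][attribute] = cols
        truth["weights"][attribute] = w.tolist()
        truth["interaction_pair"][attribute] = (cols[0], cols[-1]) if len(cols) > 1 else None
        truth["logistic_shift"][attribute] = float(rng.normal(0.2, 0.3))
    return DescriptorMatrix(frame), truth


def latent_percepts(cfg: PanelConfig, descriptors: DescriptorMatrix, truth: Mapping) -> np.ndarray:
    """Reconstruct the (n_molecules, n_attributes) latent percept matrix.

    latent = 100 * sigmoid(slope * (z @ w + g * z_i * z_j - shift)) with z
    the column-standardized informative descriptors.
    """
    attrs = cfg.attributes
    data = descriptors.data
    out = np.empty((cfg.n_molecules, len(attrs)))
    slope = truth["logistic_slope"]
    g = truth["interaction_weight"]
    for j, attribute in enumerate(attrs):
        cols = truth["informative"][attribute]
        raw = data[cols].to_numpy(dtype=float)
        z = (raw - raw.mean(axis=0)) / raw.std(axis=0)
        score = z @ np.asarray(truth["weights"][attribute])
        pair = truth["interaction_pair"][attribute]
        if pair is not None:
            zi = data[pair[0]].to_numpy(dtype=float)
            zj = data[pair[1]].to_numpy(dtype=float)
            zi = (zi - zi.mean()) / zi.std()
            zj = (zj - zj.mean()) / zj.std()
            score = score + g * zi * zj
        shift = truth["logistic_shift"][attribute]
        out[:, j] = 100.0 / (1.0 + np.exp(-slope * (score - shift)))
    return out


def _archetype_transform(kind: str, latent: np.ndarray) -> np.ndarray:
    if kind == "uniform":
        return latent
    if kind == "high_saturator":  # concave: pushes mass toward 100
        return 100.0 * (np.clip(latent, 0.0, 100.0) / 100.0) ** 0.45
    if kind == "mid_centered":  # compressive: pulls toward 50
        return 50.0 + 0.45 * (latent - 50.0)
    raise ValueError(f"unknown archetype {kind!r}")


def _make_names(
    cfg: PanelConfig, rng: np.random.Generator, latents: np.ndarray
) -> tuple[dict[int, str], dict[str, str]]:
    attrs = cfg.attributes
    semantic = [a for a in attrs if a not in ("intensity", "pleasantness")]
    letters = np.array(list("bcdfghklmnprstvz"))
    tokens: dict[str, str] = {}
    used: set[str] = set()
    for attribute in semantic:
        while True:
            tok = "".join(rng.choice(letters, 4))
            if tok not in used:
                used.add(tok)
                tokens[attribute] = tok
                break
    names: dict[int, str] = {}
    attr_index = {a: i for i, a in enumerate(attrs)}
    for m, cid in enumerate(cfg.cids):
        n_syll = int(rng.integers(1, 3))
        base = "".join(rng.choice(np.array(_SYLLABLES), n_syll)) + str(
            rng.choice(np.array(_SUFFIXES))
        )
        if rng.random() < 0.3:
            base = f"{int(rng.integers(2, 5))}-{base}"
        if cfg.name_signal and semantic:
            lat = np.array([latents[m, attr_index[a]] for a in semantic])
            strong = np.flatnonzero(lat > 55.0)
            top = strong[np.argsort(-lat[strong], kind="stable")][:2]
            for t in top:
                base = f"{base}-{tokens[semantic[t]]}"
        names[int(cid)] = base
    return names, tokens


def generate_panel(
    cfg: PanelConfig, descriptors: DescriptorMatrix, truth: dict
) -> tuple[RatingsTable, dict[int, str], dict]:
    """Rating panel + name map from descriptors and their ground truth.

    Each molecule (and each replicate) is presented at two concentrations,
    so a default-size config yields (476 + 20) * 2 = 992 stimulus rows per
    subject.  The truth dict is extended in place with latents, archetype
    assignments, odorless/violation/replicated molecule lists, and name
    tokens.
    """
    _, rng = _rngs(cfg)
    attrs = cfg.attributes
    cids = cfg.cids
    n_mol, n_sub, n_attr = cfg.n_molecules, cfg.n_subjects, len(attrs)
    has_intensity = attrs[0] == "intensity"

    latents = latent_percepts(cfg, descriptors, truth)

    n_odorless = int(round(cfg.odorless_fraction * n_mol))
    odorless_idx = rng.choice(n_mol, size=n_odorless, replace=False)
    odorless = np.zeros(n_mol, dtype=bool)
    odorless[odorless_idx] = True

    candidates = np.flatnonzero(~odorless)
    n_viol = min(int(round(cfg.violation_fraction * n_mol)), len(candidates))
    violation = np.zeros(n_mol, dtype=bool)
    violation[rng.choice(candidates, size=n_viol, replace=False)] = True

    replicated_idx = np.sort(rng.choice(n_mol, size=cfg.n_replicated, replace=False))

    archetypes = rng.choice(len(ARCHETYPES), size=n_sub, p=cfg.archetype_mix)

    # stimulus layout: (molecule or replicate) x (high, low)
    mol_idx = np.concatenate([np.arange(n_mol), replicated_idx])
    rep_flag = np.concatenate(
        [np.zeros(n_mol, dtype=np.int64), np.ones(len(replicated_idx), dtype=np.int64)]
    )
    n_pres = len(mol_idx)
    stim_mol = np.repeat(mol_idx, 2)
    stim_rep = np.repeat(rep_flag, 2)
    stim_conc = np.tile(np.array([CONCENTRATION_HIGH, CONCENTRATION_LOW], dtype=object), n_pres)
    stim_dil = np.tile(np.array([HIGH_DILUTION, LOW_DILUTION], dtype=object), n_pres)
    n_stim = len(stim_mol)  # (n_molecules + n_replicated) * 2

    # latent per stimulus row: attenuate at low concentration
    lat = latents[stim_mol]  # (n_stim, n_attr)
    low_rows = stim_conc == CONCENTRATION_LOW
    stim_lat = lat.copy()
    stim_lat[low_rows] *= 0.7
    if has_intensity:
        intensity_high = latents[stim_mol, 0]
        intensity_low = 0.6 * latents[stim_mol, 0]
        swap = violation[stim_mol]
        hi_val = np.where(swap, intensity_low, intensity_high)
        lo_val = np.where(swap, intensity_high, intensity_low)
        stim_lat[:, 0] = np.where(low_rows, lo_val, hi_val)

    values = np.empty((n_stim, n_sub, n_attr))
    for t, kind in enumerate(ARCHETYPES):
        subjects_t = np.flatnonzero(archetypes == t)
        if len(subjects_t) == 0:
            continue
        transformed = _archetype_transform(kind, stim_lat)
        values[:, subjects_t, :] = transformed[:, None, :]
    values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
    np.clip(values, 0.0, 100.0, out=values)

    odorless_rows = odorless[stim_mol]
    if has_intensity:
        values[odorless_rows, :, 0] = 0.0
        values[odorless_rows, :, 1:] = np.nan
    else:
        values[odorless_rows, :, :] = np.nan

    subjects = np.arange(1, n_sub + 1, dtype=np.int64)
    long = pd.DataFrame(
        {
            "cid": np.repeat(cids[stim_mol], n_sub * n_attr),
            "replicate": np.repeat(stim_rep, n_sub * n_attr),
            "concentration": np.repeat(stim_conc, n_sub * n_attr),
            "dilution": np.repeat(stim_dil, n_sub * n_attr),
            "subject": np.tile(np.repeat(subjects, n_attr), n_stim),
            "attribute": np.tile(np.asarray(attrs, dtype=object), n_stim * n_sub),
            "value": values.ravel(),
        }
    )
    ratings = RatingsTable(long, attrs).validate()

    names, tokens = _make_names(cfg, rng, latents)

    truth["latents"] = latents
    truth["archetypes"] = {int(s): ARCHETYPES[a] for s, a in zip(subjects, archetypes)}
    truth["odorless_cids"] = [int(c) for c in cids[odorless]]
    truth["violation_cids"] = [int(c) for c in cids[violation]]
    truth["replicated_cids"] = [int(c) for c in cids[replicated_idx]]
    truth["name_tokens"] = tokens
    return ratings, names, truth


@dataclass
class SyntheticDataset:
    """A complete generated study: descriptors, ratings, names, truth."""

    config: PanelConfig
    descriptors: DescriptorMatrix
    ratings: RatingsTable
    names: dict[int, str]
    truth: dict = field(default_factory=dict)


def generate(cfg: PanelConfig) -> SyntheticDataset:
    """Generate the full synthetic study deterministically from the seed."""
    descriptors, truth = generate_descriptors(cfg)
    ratings, names, truth = generate_panel(cfg, descriptors, truth)
    return SyntheticDataset(cfg, descriptors, ratings, names, truth)


def ground_truth_report(dataset: SyntheticDataset) -> dict:
    """Machine-readable ground truth of a generated study (JSON-able)."""
    truth = dataset.truth
    return {
        "seed": dataset.config.seed,
        "attributes": truth["attributes"],
        "informative_features": truth["informative"],
        "weights": truth["weights"],
        "interaction_pair": truth["interaction_pair"],
        "logistic_shift": truth["logistic_shift"],
        "archetypes": truth["archetypes"],
        "odorless_cids": truth["odorless_cids"],
        "violation_cids": truth["violation_cids"],
        "replicated_cids": truth["replicated_cids"],
        "name_tokens": truth["name_tokens"],
        "latents": np.round(truth["latents"], 3).tolist(),
    }
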