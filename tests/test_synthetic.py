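"""The synthetic study generator: determinism, structure, planted signal."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import odorforest as of
from odorforest import evaluate as ev
from odorforest import model as mod
from odorforest import synthetic as syn


def small_cfg(**overrides):
    base = dict(
        seed=3,
        n_molecules=30,
        n_replicated=3,
        n_subjects=4,
        n_attributes=4,
        n_descriptors=30,
        noise_sd=10.0,
    )
    base.update(overrides)
    return syn.PanelConfig(**base)


# ---------------------------------------------------------------------------
# determinism and validity


def test_generation_is_deterministic_from_seed():
    a = syn.generate(small_cfg())
    b = syn.generate(small_cfg())
    pd.testing.assert_frame_equal(a.descriptors.data, b.descriptors.data)
    pd.testing.assert_frame_equal(a.ratings.data, b.ratings.data)
    assert a.names == b.names
    assert syn.ground_truth_report(a) == syn.ground_truth_report(b)


def test_different_seeds_differ():
    a = syn.generate(small_cfg(seed=3))
    b = syn.generate(small_cfg(seed=4))
    assert not a.descriptors.data.equals(b.descriptors.data)


def test_descriptor_stage_alone_matches_full_generation():
    descriptors, truth = syn.generate_descriptors(small_cfg())
    ds = syn.generate(small_cfg())
    pd.testing.assert_frame_equal(descriptors.data, ds.descriptors.data)
    assert truth["informative"] == ds.truth["informative"]


def test_generated_panel_passes_container_validation():
    ds = syn.generate(small_cfg())
    assert ds.ratings.validate() is ds.ratings
    aligned = of.align(ds.ratings, ds.descriptors, ds.names)
    assert aligned.cids == tuple(int(c) for c in ds.descriptors.cids)


# ---------------------------------------------------------------------------
# panel structure


def test_stimulus_count_per_subject():
    cfg = small_cfg()
    ds = syn.generate(cfg)
    per_subject = ds.ratings.data[ds.ratings.data["subject"] == 1]
    n_stimuli = len(per_subject) // cfg.n_attributes
    assert n_stimuli == (cfg.n_molecules + cfg.n_replicated) * 2


def test_odorless_stimuli_have_zero_intensity_and_blank_attributes():
    ds = syn.generate(small_cfg(odorless_fraction=0.3))
    odorless = set(ds.truth["odorless_cids"])
    assert odorless
    d = ds.ratings.data
    sub = d[d["cid"].isin(odorless)]
    assert (sub.loc[sub["attribute"] == "intensity", "value"] == 0.0).all()
    assert sub.loc[sub["attribute"] != "intensity", "value"].isna().all()


def test_zero_violations_make_intensity_monotone_in_concentration():
    ds = syn.generate(
        small_cfg(noise_sd=0.0, violation_fraction=0.0, archetype_mix=(1.0, 0.0, 0.0))
    )
    d = ds.ratings.data
    sub = d[(d["attribute"] == "intensity") & ~d["cid"].isin(ds.truth["odorless_cids"])]
    wide = sub.pivot_table(
        index=["cid", "replicate", "subject"], columns="concentration", values="value"
    )
    assert (wide["high"] >= wide["low"] - 1e-9).all()


def test_violation_molecules_invert_the_concentration_effect():
    ds = syn.generate(
        small_cfg(noise_sd=0.0, violation_fraction=0.3, archetype_mix=(1.0, 0.0, 0.0))
    )
    violated = set(ds.truth["violation_cids"])
    assert violated
    d = ds.ratings.data
    sub = d[(d["attribute"] == "intensity") & d["cid"].isin(violated)]
    wide = sub.pivot_table(
        index=["cid", "replicate", "subject"], columns="concentration", values="value"
    )
    assert (wide["high"] <= wide["low"] + 1e-9).all()


def test_noise_free_uniform_panel_has_zero_intersubject_cv():
    ds = syn.generate(
        small_cfg(noise_sd=0.0, archetype_mix=(1.0, 0.0, 0.0), odorless_fraction=0.0)
    )
    for attribute in ds.ratings.attributes:
        assert ev.coefficient_of_variation(ds.ratings, attribute) == pytest.approx(0.0, abs=1e-12)


def test_archetype_mix_shapes_rating_distributions():
    ds = syn.generate(
        small_cfg(n_subjects=30, noise_sd=5.0, archetype_mix=(0.0, 0.5, 0.5), seed=8)
    )
    d = ds.ratings.data
    d = d[(d["attribute"] != "intensity") & d["value"].notna()]
    by_subject = d.groupby("subject")["value"].mean()
    arch = ds.truth["archetypes"]
    saturators = [s for s, a in arch.items() if a == "high_saturator"]
    centered = [s for s, a in arch.items() if a == "mid_centered"]
    assert by_subject[saturators].mean() > by_subject[centered].mean()


def test_replicated_molecules_appear_twice():
    ds = syn.generate(small_cfg())
    replicated = set(ds.truth["replicated_cids"])
    d = ds.ratings.data
    assert set(d.loc[d["replicate"] == 1, "cid"]) == replicated


# ---------------------------------------------------------------------------
# descriptors and planted signal


def test_degenerate_features_have_few_distinct_values():
    ds = syn.generate(small_cfg())
    degenerate = [c for c in ds.descriptors.columns if c.startswith("nX")]
    assert degenerate
    for col in degenerate:
        assert ds.descriptors.data[col].nunique() <= 10


def test_informative_features_correlate_with_latents_noise_does_not():
    ds = syn.generate(small_cfg(n_molecules=60))
    latents = ds.truth["latents"]
    attrs = list(ds.ratings.attributes)
    noise_cols = [c for c in ds.descriptors.columns if c.startswith("Eig")]
    for j, attribute in enumerate(attrs):
        informative = ds.truth["informative"][attribute]
        r_inf = max(
            abs(stats.pearsonr(ds.descriptors.data[c], latents[:, j]).statistic)
            for c in informative
        )
        assert r_inf > 0.3
    r_noise = np.mean(
        [
            abs(stats.pearsonr(ds.descriptors.data[c], latents[:, 0]).statistic)
            for c in noise_cols
        ]
    )
    assert r_noise < 0.2  # Monte-Carlo band for n=60


def test_truth_report_structure():
    cfg = small_cfg()
    ds = syn.generate(cfg)
    report = syn.ground_truth_report(ds)
    for attribute in ds.ratings.attributes:
        assert len(report["informative_features"][attribute]) == cfg.n_informative
    assert len(report["archetypes"]) == cfg.n_subjects
    assert len(report["latents"]) == cfg.n_molecules


def test_config_validation():
    with pytest.raises(ValueError):
        syn.PanelConfig(seed=0, n_descriptors=10, n_attributes=4, n_informative=20)
    with pytest.raises(ValueError):
        syn.PanelConfig(seed=0, archetype_mix=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        syn.PanelConfig(seed=0, odorless_fraction=1.5)
    with pytest.raises(ValueError):
        syn.PanelConfig(seed=0, n_replicated=1000)


def test_names_embed_tokens_for_strong_semantic_attributes():
    ds = syn.generate(small_cfg(n_molecules=60))
    tokens = ds.truth["name_tokens"]
    latents = ds.truth["latents"]
    attrs = list(ds.ratings.attributes)
    hits = 0
    for attribute, token in tokens.items():
        j = attrs.index(attribute)
        strong = [int(c) for c, lat in zip(ds.descriptors.cids, latents[:, j]) if lat > 55]
        if strong:
            hits += sum(token in ds.names[c] for c in strong)
    assert hits > 0


def test_pipeline_beats_permuted_label_null():
    """CV predictions correlate with observations far above the shuffled null."""
    ds = syn.generate(small_cfg(n_molecules=40, seed=6))
    aligned = of.align(ds.ratings, ds.descriptors, ds.names)
    plan = ev.make_cv_plan(aligned.cids, k=5, seed=0)
    scores = ev.cross_validate(aligned, spec=mod.LearnerSpec(n_trees=30, seed=0), plan=plan)
    observed_mean = scores.overall_mean()

    # permutation null: shuffle observed ratings across molecules within
    # (subject, attribute), re-score the same predictions
    obs = ev.observed_targets(aligned.ratings)
    pred_frames = []
    for fold, (train_cids, test_cids) in enumerate(plan.folds()):
        tensor = ev._fold_predictions(
            aligned, train_cids, test_cids, mod.LearnerSpec(n_trees=30, seed=0),
            mod.BlendSpec(0.2), "molecular", None, None, "1/1,000", True, 4, "strict",
            (0.5, 0.5),
        )
        pred_frames.append(tensor.to_frame().rename(columns={"value": "predicted"}))
    pred = pd.concat(pred_frames, ignore_index=True)
    merged = obs.merge(pred, on=["cid", "subject", "attribute"], how="inner")

    rng = np.random.default_rng(0)
    null_means = []
    for _ in range(199):
        shuffled = merged.copy()
        shuffled["observed"] = (
            shuffled.groupby(["subject", "attribute"])["observed"]
            .transform(lambda v: rng.permutation(v.to_numpy()))
        )
        rs = [
            ev.pearson(g["observed"], g["predicted"])
            for _, g in shuffled.groupby("attribute")
        ]
        null_means.append(np.nanmean(rs))
    exceed = sum(1 for m in null_means if m >= observed_mean)
    p_value = (exceed + 1) / (len(null_means) + 1)
    assert p_value < 0.01
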