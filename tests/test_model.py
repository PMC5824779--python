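"""Target blending, the model matrix, population predictions, baselines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from odorforest import model as mod
from odorforest import preprocess as pp
from odorforest.io import POPULATION_SUBJECT, ValidationError


def make_examples(n_subjects, attributes, n_molecules=8, seed=0):
    """Synthetic example set: every (subject, attribute) has one example
    per molecule (provenance high)."""
    rng = np.random.default_rng(seed)
    rows = []
    for subject in range(1, n_subjects + 1):
        for attribute in attributes:
            for cid in range(101, 101 + n_molecules):
                rows.append(
                    {"subject": subject, "attribute": attribute, "cid": cid,
                     "replicate": 0, "provenance": pp.PROVENANCE_HIGH,
                     "target": float(rng.uniform(0, 100))}
                )
    return pp.ExampleSet(pd.DataFrame(rows), tuple(attributes))


def make_features(n_molecules=8, n_features=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(size=(n_molecules, n_features)),
        index=pd.Index(range(101, 101 + n_molecules), name="cid"),
        columns=[f"d{i}" for i in range(n_features)],
    )


# ---------------------------------------------------------------------------
# population target and blending


def test_population_target_ignores_missing():
    assert mod.population_target([0.0, 100.0, np.nan]) == 50.0
    assert np.isnan(mod.population_target([np.nan, np.nan]))


def test_population_target_matches_brute_force_mean():
    rng = np.random.default_rng(4)
    for _ in range(20):
        v = rng.uniform(0, 100, size=10)
        v[rng.random(10) < 0.3] = np.nan
        expected = v[~np.isnan(v)].mean() if (~np.isnan(v)).any() else np.nan
        got = mod.population_target(v)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_blend_worked_example_and_endpoints():
    b = mod.BlendSpec(alpha=0.2)
    assert mod.blend_targets(100.0, 50.0, b) == pytest.approx(60.0, abs=1e-12)
    assert mod.blend_targets(77.0, 12.0, mod.BlendSpec(0.0)) == 12.0
    assert mod.blend_targets(77.0, 12.0, mod.BlendSpec(1.0)) == 77.0


def test_alpha_outside_unit_interval_is_rejected():
    with pytest.raises(ValueError):
        mod.BlendSpec(alpha=1.2)
    with pytest.raises(ValueError):
        mod.BlendSpec(alpha=-0.1)


@given(
    st.floats(0, 100, allow_nan=False),
    st.floats(0, 100, allow_nan=False),
    st.floats(0, 1, allow_nan=False),
)
def test_blend_linearity_and_bounds(y_ind, y_pop, alpha):
    y = mod.blend_targets(y_ind, y_pop, mod.BlendSpec(alpha))
    assert y == pytest.approx(alpha * y_ind + (1 - alpha) * y_pop, abs=1e-9)
    assert min(y_ind, y_pop) - 1e-9 <= y <= max(y_ind, y_pop) + 1e-9


@given(st.floats(0, 100), st.floats(0, 100))
def test_blend_is_monotone_in_alpha(y_ind, y_pop):
    alphas = np.linspace(0, 1, 6)
    blends = [mod.blend_targets(y_ind, y_pop, mod.BlendSpec(a)) for a in alphas]
    diffs = np.diff(blends)
    assert (diffs >= -1e-9).all() or (diffs <= 1e-9).all()


# ---------------------------------------------------------------------------
# model matrix


@pytest.mark.parametrize("n_subjects,attributes", [(1, ("sweet",)), (2, ("a", "b", "c"))])
def test_one_model_per_subject_attribute_pair(n_subjects, attributes):
    examples = make_examples(n_subjects, attributes)
    mm = mod.train_model_matrix(
        examples, make_features(), spec=mod.LearnerSpec(n_trees=2, seed=0)
    )
    assert mm.n_individual_models == n_subjects * len(attributes)
    assert set(mm.population_models) == set(attributes)


def test_alpha_zero_gives_identical_predictions_across_subjects():
    examples = make_examples(3, ("sweet", "fish"))
    features = make_features()
    mm = mod.train_model_matrix(
        examples, features, spec=mod.LearnerSpec(n_trees=5, seed=1), blend=mod.BlendSpec(0.0)
    )
    tensor = mod.predict_matrix(mm, features)
    for j in range(tensor.values.shape[2]):
        layer = tensor.values[:, :, j]
        assert np.allclose(layer, layer[:, [0]])


def test_constant_target_forest_predicts_the_constant():
    examples = make_examples(1, ("sweet",))
    examples.data["target"] = 42.0
    features = make_features()
    mm = mod.train_model_matrix(examples, features, spec=mod.LearnerSpec(n_trees=3, seed=0))
    tensor = mod.predict_matrix(mm, make_features(seed=99))
    np.testing.assert_allclose(tensor.values, 42.0)


def test_predictions_stay_on_rating_scale():
    examples = make_examples(2, ("sweet",), seed=3)
    features = make_features(seed=3)
    mm = mod.train_model_matrix(examples, features, spec=mod.LearnerSpec(n_trees=5, seed=2))
    tensor = mod.predict_matrix(mm, make_features(seed=7) * 100)
    assert tensor.values.min() >= 0.0 and tensor.values.max() <= 100.0


def test_training_is_reproducible_given_seed():
    examples = make_examples(2, ("sweet", "fish"), seed=5)
    features = make_features(seed=5)
    spec = mod.LearnerSpec(n_trees=10, seed=7)
    t1 = mod.predict_matrix(mod.train_model_matrix(examples, features, spec=spec), features)
    t2 = mod.predict_matrix(mod.train_model_matrix(examples, features, spec=spec), features)
    np.testing.assert_array_equal(t1.values, t2.values)


def test_per_model_seeds_differ_but_derive_from_base():
    s1 = mod.model_seed(0, 1, "sweet")
    s2 = mod.model_seed(0, 2, "sweet")
    s3 = mod.model_seed(0, 1, "fish")
    assert len({s1, s2, s3}) == 3
    assert all(0 <= s < 2**31 for s in (s1, s2, s3))


def test_sparse_pairs_are_skipped_with_population_fallback():
    examples = make_examples(2, ("sweet",), n_molecules=8)
    data = examples.data
    # subject 2 keeps only 3 examples -> below the min_examples floor of 5
    keep = (data["subject"] == 1) | (data["cid"] <= 103)
    examples = pp.ExampleSet(data[keep].reset_index(drop=True), examples.attributes)
    features = make_features()
    with pytest.warns(UserWarning, match="skipped"):
        mm = mod.train_model_matrix(examples, features, spec=mod.LearnerSpec(n_trees=2, seed=0))
    assert mm.skipped == ((2, "sweet"),)
    tensor = mod.predict_matrix(mm, features)
    pop = mod.predict_population(mm, features)
    np.testing.assert_array_equal(tensor.values[:, 1, 0], pop.values[:, 0, 0])


def test_feature_signature_mismatch_is_rejected():
    examples = make_examples(1, ("sweet",))
    features = make_features()
    mm = mod.train_model_matrix(examples, features, spec=mod.LearnerSpec(n_trees=2, seed=0))
    wrong = features.rename(columns={"d0": "other"})
    with pytest.raises(ValidationError, match="signature"):
        mod.predict_matrix(mm, wrong)


# ---------------------------------------------------------------------------
# population predictions and ensembling


def test_population_modes_coincide_for_single_subject():
    examples = make_examples(1, ("sweet", "fish"), seed=2)
    features = make_features(seed=2)
    mm = mod.train_model_matrix(
        examples, features, spec=mod.LearnerSpec(n_trees=5, seed=0), blend=mod.BlendSpec(0.0)
    )
    a = mod.predict_population(mm, features, mode="population_model")
    b = mod.predict_population(mm, features, mode="average_individuals")
    np.testing.assert_allclose(a.values, b.values, atol=1e-9)
    assert a.scope == b.scope == "population"
    assert a.subjects == (POPULATION_SUBJECT,)


def test_average_individuals_is_the_mean_of_subject_layers():
    examples = make_examples(3, ("sweet",), seed=6)
    features = make_features(seed=6)
    mm = mod.train_model_matrix(examples, features, spec=mod.LearnerSpec(n_trees=5, seed=1))
    individual = mod.predict_matrix(mm, features)
    pop = mod.predict_population(mm, features, mode="average_individuals")
    np.testing.assert_allclose(pop.values[:, 0, :], individual.values.mean(axis=1))


def _tensor(values, attributes=("sweet",)):
    values = np.asarray(values, dtype=float)
    return mod.PredictionTensor(
        values, range(1, values.shape[0] + 1), range(1, values.shape[1] + 1), attributes
    )


def test_ensemble_weighting():
    a = _tensor([[[40.0]], [[80.0]]])
    b = _tensor([[[60.0]], [[0.0]]])
    only_a = mod.ensemble_predict(a, b, weights=(1.0, 0.0))
    np.testing.assert_array_equal(only_a.values, a.values)
    half = mod.ensemble_predict(a, b, weights=(0.5, 0.5))
    np.testing.assert_array_equal(half.values.ravel(), [50.0, 40.0])


def test_ensemble_is_convex_and_validates_index():
    rng = np.random.default_rng(8)
    a = _tensor(rng.uniform(0, 100, (3, 2, 1)))
    b = _tensor(rng.uniform(0, 100, (3, 2, 1)))
    out = mod.ensemble_predict(a, b, weights=(2.0, 1.0))
    assert (out.values >= np.minimum(a.values, b.values) - 1e-12).all()
    assert (out.values <= np.maximum(a.values, b.values) + 1e-12).all()
    c = _tensor(rng.uniform(0, 100, (3, 2, 1)), attributes=("fish",))
    with pytest.raises(ValidationError):
        mod.ensemble_predict(a, c)
    with pytest.raises(ValueError):
        mod.ensemble_predict(a, b, weights=(-1.0, 0.5))


# ---------------------------------------------------------------------------
# baselines


def test_ridge_matches_closed_form_solution():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(20, 3))
    y = rng.normal(size=20)
    est = mod.fit_baseline("ridge", X, y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = np.linalg.solve(Xc.T @ Xc + 10.0 * np.eye(3), Xc.T @ yc)
    np.testing.assert_allclose(est.coef_, w, atol=1e-10)


def test_ridge_with_tiny_penalty_recovers_slope():
    x = np.arange(10, dtype=float).reshape(-1, 1)
    est = mod.fit_baseline("ridge", x, 3.0 * x.ravel(), spec=mod.LearnerSpec(ridge_alpha=1e-8))
    assert est.coef_[0] == pytest.approx(3.0, abs=1e-6)


def test_linear_fit_survives_exact_collinearity():
    x = np.arange(6, dtype=float)
    X = np.column_stack([x, 2 * x])  # rank 1
    est = mod.fit_baseline("linear", X, 5.0 * x)
    assert np.isfinite(est.coef_).all()
    np.testing.assert_allclose(est.predict(X), 5.0 * x, atol=1e-8)


def test_default_hyperparameters_follow_the_method():
    spec = mod.LearnerSpec()
    assert spec.n_trees == 100
    assert spec.ridge_alpha == 10.0
    assert spec.svr_c == 1000.0 and spec.svr_gamma == 0.01
    svr = mod.make_estimator(mod.LearnerSpec(kind="svr_rbf"))
    assert svr.C == 1000.0 and svr.gamma == 0.01
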