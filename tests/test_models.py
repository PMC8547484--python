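"""Per-taxon two-stage model: selection, transforms, ensemble, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit as sp_logit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_predict, train_test_split

from cytotax.models import (
    ModelParams,
    compute_zero_replacement,
    feature_importance,
    load_model,
    logit_forward,
    logit_inverse,
    predict_taxon,
    save_model,
    select_features,
    train_classifier,
    train_regressor,
    train_taxon_model,
)

FAST = ModelParams(n_trees=100, rfe_trees=50, gbr_trees=100)


def _frame(values, prefix="c"):
    values = np.asarray(values)
    return pd.DataFrame(values, columns=[f"{prefix}{j:03d}" for j in range(values.shape[1])])


@pytest.fixture(scope="module")
def separable():
    """One perfectly separating feature plus nine noise features."""
    rng = np.random.default_rng(0)
    n = 120
    y = np.arange(n) % 2 == 0
    X = rng.normal(size=(n, 10))
    X[:, 4] = np.where(y, 3.0, -3.0) + rng.normal(0, 0.3, size=n)
    return _frame(X), y


class TestSelectFeatures:
    def test_perfect_feature_selected_alone(self, separable):
        X, y = separable
        selected = select_features(X, y, FAST, seed=0)
        assert selected == ["c004"]

    def test_pure_noise_returns_smallest_subset(self, rng):
        X = _frame(rng.normal(size=(80, 6)))
        y = rng.uniform(size=80) < 0.5
        selected = select_features(X, y, FAST, seed=0)
        # flat profile within tolerance -> minimum size wins
        assert len(selected) == 1

    def test_zero_tolerance_takes_profile_maximum(self, separable):
        X, y = separable
        params = ModelParams(n_trees=100, rfe_trees=50, rfe_tolerance=0.0)
        selected = select_features(X, y, params, seed=0)
        best = select_features(X, y, FAST, seed=0)
        assert set(best) <= set(selected) or len(selected) >= len(best)

    def test_single_class_rejected(self, rng):
        X = _frame(rng.normal(size=(30, 4)))
        with pytest.raises(ValueError, match="single-class"):
            select_features(X, np.ones(30, dtype=bool), FAST, seed=0)


class TestClassifier:
    def test_separated_clouds_auc(self, separable):
        X, y = separable
        clf = train_classifier(X[["c004"]], y, FAST, seed=0)
        prob = clf.predict_proba(X[["c004"]].to_numpy())[:, list(clf.classes_).index(True)]
        assert roc_auc_score(y, prob) >= 0.99

    def test_shuffled_labels_give_chance_auc(self, rng):
        X = _frame(rng.normal(size=(150, 6)))
        aucs = []
        for rep in range(10):
            y = rng.permutation(np.arange(150) % 2 == 0)
            clf = train_classifier(X, y, FAST, seed=rep)
            prob = cross_val_predict(
                clf, X.to_numpy(), y, cv=5, method="predict_proba"
            )[:, 1]
            aucs.append(roc_auc_score(y, prob))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_rejected(self, rng):
        X = _frame(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError):
            train_classifier(X, np.zeros(20, dtype=bool), FAST, seed=0)


class TestLogit:
    def test_midpoint(self):
        assert logit_forward(np.array([0.5]), 0.001)[0] == 0.0

    def test_zero_replacement_value(self):
        t = np.array([0.0, 0.02])
        zr = compute_zero_replacement(t)
        assert zr == pytest.approx(0.002)
        out = logit_forward(t, zr)
        assert out[0] == pytest.approx(np.log(0.002 / 0.998), abs=1e-4)
        assert out[0] == pytest.approx(-6.2126, abs=1e-3)

    def test_round_trip(self, rng):
        x = rng.uniform(1e-6, 1 - 1e-6, size=1000)
        back = logit_inverse(logit_forward(x, 1e-9))
        np.testing.assert_allclose(back, x, atol=1e-12)

    def test_matches_scipy_on_nonzero(self, rng):
        x = rng.uniform(0.01, 0.99, size=50)
        np.testing.assert_allclose(logit_forward(x, 1e-3), sp_logit(x))

    def test_value_at_one_rejected(self):
        with pytest.raises(ValueError):
            logit_forward(np.array([1.0]), 0.01)

    def test_extreme_logits_stay_bounded(self):
        out = logit_inverse(np.array([-50.0, 50.0]))
        assert 0.0 <= out[0] <= 1.0 and 0.0 <= out[1] <= 1.0

    def test_all_zero_training_rejected(self):
        with pytest.raises(ValueError):
            compute_zero_replacement(np.zeros(5))


class TestRegressor:
    def test_noiseless_linear_target(self, rng):
        X = _frame(rng.uniform(-2, 2, size=(150, 3)))
        t = 1.5 * X["c000"].to_numpy() - 0.3
        Xtr, Xte, ttr, tte = train_test_split(X, t, test_size=40, random_state=0)
        stack = train_regressor(Xtr, ttr, FAST, seed=0)
        pred = stack.predict(Xte.to_numpy())
        ss = 1 - np.sum((tte - pred) ** 2) / np.sum((tte - tte.mean()) ** 2)
        assert ss >= 0.99

    def test_noise_target_has_no_holdout_skill(self, rng):
        scores = []
        for rep in range(5):
            X = _frame(rng.normal(size=(120, 4)))
            t = rng.normal(size=120)
            Xtr, Xte, ttr, tte = train_test_split(X, t, test_size=40, random_state=rep)
            stack = train_regressor(Xtr, ttr, FAST, seed=rep)
            pred = stack.predict(Xte.to_numpy())
            scores.append(1 - np.sum((tte - pred) ** 2) / np.sum((tte - tte.mean()) ** 2))
        assert np.mean(scores) <= 0.1

    def test_stack_weights_finite_and_predictive(self, rng):
        X = _frame(rng.uniform(-1, 1, size=(100, 2)))
        t = X["c000"].to_numpy() ** 2
        stack = train_regressor(X, t, FAST, seed=0)
        assert np.all(np.isfinite(stack.combiner.coef_))
        assert np.isfinite(stack.combiner.intercept_)

    def test_constant_target_rejected(self, rng):
        X = _frame(rng.normal(size=(30, 2)))
        with pytest.raises(ValueError, match="constant"):
            train_regressor(X, np.full(30, 0.7), FAST, seed=0)


@pytest.fixture(scope="module")
def hurdle_model():
    """A trained two-stage model on a simple hurdle-style dataset."""
    rng = np.random.default_rng(7)
    n = 140
    present = rng.uniform(size=n) < 0.5
    X = _frame(rng.normal(size=(n, 6)))
    X["c002"] += np.where(present, 2.5, 0.0)
    t = np.where(present, 0.05 + 0.2 * (X["c002"] - X["c002"].min())
                 / (X["c002"].max() - X["c002"].min()), 0.0)
    model = train_taxon_model(X, t, "otu_test", FAST, seed=0)
    return model, X, t


class TestTaxonModel:
    def test_superimposition_zeroes_absent_predictions(self, hurdle_model):
        model, X, t = hurdle_model
        preds = predict_taxon(model, X)
        absent = ~preds["presence"]
        assert (preds.loc[absent, "rel_abundance"] == 0.0).all()
        present = preds["presence"]
        np.testing.assert_allclose(
            preds.loc[present, "rel_abundance"], preds.loc[present, "rel_raw"]
        )

    def test_superimposition_never_increases_and_is_idempotent(self, hurdle_model):
        model, X, _ = hurdle_model
        preds = predict_taxon(model, X)
        assert (preds["rel_abundance"] <= preds["rel_raw"] + 1e-15).all()
        again = np.where(preds["presence"], preds["rel_abundance"], 0.0)
        np.testing.assert_array_equal(again, preds["rel_abundance"].to_numpy())

    def test_predictions_bounded(self, hurdle_model):
        model, X, _ = hurdle_model
        preds = predict_taxon(model, X)
        assert preds["rel_raw"].between(0, 1).all()
        assert preds["rel_abundance"].between(0, 1).all()

    def test_inverse_logit_example(self):
        assert logit_inverse(np.array([-2.1972]))[0] == pytest.approx(0.10, abs=1e-4)

    def test_densities_optional(self, hurdle_model):
        from cytotax.taxa import DensitySeries

        model, X, _ = hurdle_model
        no_dens = predict_taxon(model, X)
        assert "abs_abundance" not in no_dens.columns
        dens = DensitySeries(pd.Series(1e6, index=X.index))
        with_dens = predict_taxon(model, X, dens)
        np.testing.assert_allclose(
            with_dens["abs_abundance"], with_dens["rel_abundance"] * 1e6
        )

    def test_feature_mismatch_rejected(self, hurdle_model):
        model, X, _ = hurdle_model
        with pytest.raises(ValueError, match="mismatch"):
            predict_taxon(model, X.rename(columns={"c002": "weird"}))

    def test_bundle_round_trip_bitwise(self, hurdle_model, tmp_path):
        model, X, _ = hurdle_model
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        a = predict_taxon(model, X)
        b = predict_taxon(back, X)
        pd.testing.assert_frame_equal(a, b)
        assert back.zero_replacement == model.zero_replacement
        assert back.selected_features == model.selected_features

    def test_zero_replacement_stored_from_training(self, hurdle_model):
        model, _, t = hurdle_model
        assert model.zero_replacement == pytest.approx(t[t > 0].min() / 10)
        assert model.zero_replacement < t[t > 0].min()


class TestImportances:
    def test_informative_feature_ranks_first_everywhere(self, hurdle_model):
        model, _, _ = hurdle_model
        imps = feature_importance(model)
        for sub in ("classifier", "gbm", "svr"):
            ranked = sorted(imps[sub], key=imps[sub].get, reverse=True)
            assert ranked[0] == "c002", sub

    def test_unselected_clusters_zero_in_classifier(self, hurdle_model):
        model, _, _ = hurdle_model
        imps = feature_importance(model)
        for feat in set(model.all_features) - set(model.selected_features):
            assert imps["classifier"][feat] == 0.0

    def test_normalized_to_unit_interval(self, hurdle_model):
        model, _, _ = hurdle_model
        imps = feature_importance(model)
        for sub, vals in imps.items():
            arr = np.array(list(vals.values()))
            assert arr.min() >= 0.0 and arr.max() <= 1.0
            assert arr.max() == pytest.approx(1.0)
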