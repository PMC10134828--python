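"""Model training contract, naive baselines and copy models."""

import numpy as np
import pandas as pd
import pytest

from pairfx.models import (
    ModelSpec,
    fit_null_model,
    fit_threshold_model,
    metabolic_copy_predict,
    phylo_copy_predict,
    tune_and_train,
)
from pairfx.growth import InteractionDataset

from conftest import TINY_PARAMS, make_conserved_twin_dataset


def _xy(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["f1", "f2", "f3"])
    y = X["f1"].to_numpy() * 2 - 1 + rng.normal(0, 0.1, size=n)
    return X, y


class TestTuneAndTrain:
    def test_budget_one_uses_single_sampled_config(self):
        X, y = _xy()
        spec = ModelSpec(family="gradient_boosted_trees", task="strength",
                         budget=1, cv_folds=3, seed=0)
        model = tune_and_train(spec, X, y)
        assert model.cv_score is not None
        assert set(model.best_params) == {
            "n_estimators", "max_depth", "learning_rate", "subsample",
            "colsample_bytree", "reg_lambda"}

    def test_dominant_configuration_selected(self):
        # exact 1-NN dominates a large k on noiseless deterministic data
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.uniform(0, 10, 200)})
        y = 3.0 * X["x"].to_numpy()
        spec = ModelSpec(family="k_nearest_neighbors", task="strength",
                         param_space={"est__n_neighbors": [1, 50],
                                      "est__weights": ["uniform"]},
                         budget=2, cv_folds=3, seed=0)
        model = tune_and_train(spec, X, y)
        assert model.best_params["est__n_neighbors"] == 1

    def test_single_class_sign_labels_rejected(self):
        X, _ = _xy()
        y = np.array(["negative"] * len(X))
        spec = ModelSpec(family="gradient_boosted_trees", task="sign", budget=1)
        with pytest.raises(ValueError, match="degenerate labels"):
            tune_and_train(spec, X, y)

    def test_boosted_model_beats_null_on_planted_signal(self, small_features):
        X, y = small_features
        spec = ModelSpec(family="gradient_boosted_trees", task="strength",
                         fixed_params=TINY_PARAMS, seed=0)
        model = tune_and_train(spec, X, y["effect"].to_numpy())
        null = fit_null_model(ModelSpec(family="null", task="strength"),
                              X, y["effect"].to_numpy())
        resid_m = np.mean((model.predict(X) - y["effect"]) ** 2)
        resid_n = np.mean((null.predict(X) - y["effect"]) ** 2)
        assert resid_m < resid_n

    def test_reproducible_given_seed(self):
        X, y = _xy()
        spec = ModelSpec(family="gradient_boosted_trees", task="strength",
                         budget=3, cv_folds=3, seed=5)
        m1, m2 = tune_and_train(spec, X, y), tune_and_train(spec, X, y)
        assert m1.best_params == m2.best_params
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_schema_mismatch_rejected(self):
        X, y = _xy()
        spec = ModelSpec(family="linear", task="strength", budget=1)
        model = tune_and_train(spec, X, y)
        with pytest.raises(ValueError, match="schema"):
            model.predict(X.rename(columns={"f1": "other"}))

    def test_two_way_predicts_effect_pairs(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
        y2 = np.column_stack([X["a"], -X["a"]]) + rng.normal(0, 0.05, (80, 2))
        spec = ModelSpec(family="gradient_boosted_trees", task="two_way_strength",
                         fixed_params=TINY_PARAMS, seed=0)
        model = tune_and_train(spec, X, y2)
        pred = model.predict(X)
        assert pred.shape == (80, 2)


class TestNullModel:
    def test_strength_prediction_is_training_mean(self):
        X, y = _xy()
        model = fit_null_model(ModelSpec(family="null", task="strength"), X, y)
        np.testing.assert_allclose(model.predict(X), y.mean())

    def test_sign_prediction_is_most_frequent(self):
        X, _ = _xy(n=10)
        y = np.array(["negative"] * 7 + ["positive"] * 3)
        model = fit_null_model(ModelSpec(family="null", task="sign"), X, y)
        assert (model.predict(X) == "negative").all()
        assert model.train_summary["most_frequent_sign"] == "negative"

    def test_invariant_to_feature_values(self):
        X, y = _xy()
        model = fit_null_model(ModelSpec(family="null", task="strength"), X, y)
        shuffled = X.sample(frac=1.0, random_state=0).reset_index(drop=True)
        np.testing.assert_array_equal(model.predict(X), model.predict(shuffled))


def brute_force_threshold(x, y):
    """Independent exhaustive search over all midpoints x directions."""
    uniq = np.unique(x)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best = -1.0
    for t in cands:
        for high in ("negative", "positive"):
            low = "positive" if high == "negative" else "negative"
            pred = np.where(x >= t, high, low)
            best = max(best, float(np.mean(pred == y)))
    return best


class TestThresholdModel:
    def test_separable_labels(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        y = np.array(["positive", "positive", "negative", "negative"])
        model = fit_threshold_model("f", X, y)
        assert model.best_params["threshold"] == pytest.approx(2.5)
        assert (model.predict(X) == y).all()

    def test_all_negative_labels_fit_degenerately(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        y = np.array(["negative"] * 3)
        model = fit_threshold_model("f", X, y)
        assert (model.predict(X) == "negative").all()
        assert model.cv_score == 1.0

    def test_constant_feature_degrades_to_null(self):
        X = pd.DataFrame({"f": [1.0, 1.0, 1.0]})
        y = np.array(["negative", "negative", "positive"])
        with pytest.warns(UserWarning, match="constant feature"):
            model = fit_threshold_model("f", X, y)
        assert (model.predict(X) == "negative").all()

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = np.where(rng.random(30) < 0.6, "negative", "positive")
            X = pd.DataFrame({"f": x})
            model = fit_threshold_model("f", X, y)
            acc = float(np.mean(model.predict(X) == y))
            assert acc == pytest.approx(brute_force_threshold(x, y))


class TestCopyModels:
    def test_twin_record_returned_verbatim(self):
        ds = make_conserved_twin_dataset()
        lookup = ds.effect_lookup()
        for key in [k for k in lookup if k[0] == "T"]:
            v = phylo_copy_predict(ds, key, uncultured="T")
            assert v == lookup[("S1", key[1], key[2])]

    def test_fallback_to_next_closest_when_missing(self):
        ds = make_conserved_twin_dataset()
        # remove the twin's matching record so the next-closest must be used
        key = ("T", "P1", "C1")
        eff = ds.effects
        mask = ~((eff["affected"] == "S1") & (eff["affecting"] == "P1")
                 & (eff["carbon"] == "C1"))
        ds2 = InteractionDataset(effects=eff[mask].reset_index(drop=True),
                                 mono_yields=ds.mono_yields,
                                 phylo_dist=ds.phylo_dist)
        v = phylo_copy_predict(ds2, key, uncultured="T")
        # next-closest species with a matching record is P2 (distance 2)
        assert v == ds2.effect_lookup()[("P2", "P1", "C1")]

    def test_no_copyable_interaction_raises(self):
        ds = make_conserved_twin_dataset()
        eff = ds.effects[ds.effects["carbon"] != "C1"].reset_index(drop=True)
        ds2 = InteractionDataset(effects=eff, mono_yields=ds.mono_yields,
                                 phylo_dist=ds.phylo_dist)
        with pytest.raises(LookupError, match="no copyable"):
            phylo_copy_predict(ds2, ("T", "P1", "C1"), uncultured="T")

    def test_metabolic_ranking_matches_bruteforce_sort(self, small_dataset):
        ds, _ = small_dataset
        prof = ds.imputed_profiles()
        carbon = ds.carbons[0]
        target = prof[carbon].to_numpy()
        order = sorted(
            (c for c in ds.carbons if c != carbon),
            key=lambda c: (float(np.linalg.norm(prof[c].to_numpy() - target)), c),
        )
        rec = ds.effects[ds.effects["carbon"] == carbon].iloc[0]
        v = metabolic_copy_predict(ds, (rec.affected, rec.affecting, carbon),
                                   excluded_carbon=carbon)
        lookup = ds.effect_lookup()
        expected = next(
            lookup[(rec.affected, rec.affecting, c)] for c in order
            if (rec.affected, rec.affecting, c) in lookup
        )
        assert v == expected

    def test_duplicate_carbon_copied_exactly(self):
        ds = make_conserved_twin_dataset()
        # make C2 a duplicate environment of C1 in both profile and effects
        mono = ds.mono_yields.copy()
        mono["C2"] = mono["C1"]
        eff = ds.effects.copy()
        c1 = eff[eff["carbon"] == "C1"].copy()
        eff = eff[eff["carbon"] != "C2"]
        dup = c1.assign(carbon="C2")
        ds2 = InteractionDataset(
            effects=pd.concat([eff, dup], ignore_index=True),
            mono_yields=mono, phylo_dist=ds.phylo_dist)
        lookup = ds2.effect_lookup()
        key = ("T", "P1", "C2")
        assert metabolic_copy_predict(ds2, key, excluded_carbon="C2") == \
            lookup[("T", "P1", "C1")]
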