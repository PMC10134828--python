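"""Splits, metric definitions and the leave-one-out ablation harness."""

import numpy as np
import pandas as pd
import pytest

from pairfx.evaluation import (
    _leakage_guard,
    _variant_columns,
    classification_metrics,
    error_vs_strength_profile,
    loo_species_ablation,
    regression_metrics,
    split_train_test,
)
from pairfx.models import ModelSpec, phylo_copy_predict

from conftest import TINY_PARAMS, make_conserved_twin_dataset


def _effects(n=100, neg_frac=0.76, seed=0):
    rng = np.random.default_rng(seed)
    sign = np.where(rng.random(n) < neg_frac, "negative", "positive")
    eff = np.where(sign == "negative", -1.0, 1.0) * rng.uniform(0.1, 1, n)
    return pd.DataFrame({
        "affected": [f"A{i}" for i in range(n)],
        "affecting": "B", "carbon": "C1", "effect": eff, "sign": sign,
    })


class TestSplit:
    def test_eighty_twenty_sizes(self):
        train, test = split_train_test(_effects(100), test_frac=0.2, seed=0)
        assert (len(train), len(test)) == (80, 20)

    def test_disjoint_and_exhaustive(self):
        eff = _effects(60)
        train, test = split_train_test(eff, seed=1)
        combined = pd.concat([train, test]).sort_values("affected")
        pd.testing.assert_frame_equal(
            combined.reset_index(drop=True),
            eff.sort_values("affected").reset_index(drop=True))

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(_effects(10), test_frac=0.999)
        with pytest.raises(ValueError):
            split_train_test(_effects(10), test_frac=0.01)

    def test_stratification_preserves_imbalance(self):
        eff = _effects(200, neg_frac=0.76, seed=2)
        _, test = split_train_test(eff, test_frac=0.2, seed=0)
        expected = (eff["sign"] == "negative").sum() * 0.2
        assert abs((test["sign"] == "negative").sum() - expected) <= 2


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = ["positive", "negative", "negative"]
        m = classification_metrics(y, y)
        assert m["accuracy"] == 1.0 and m["mcc"] == 1.0

    def test_no_association(self):
        yt = ["positive", "positive", "negative", "negative"]
        yp = ["positive", "negative", "positive", "negative"]
        assert classification_metrics(yt, yp)["mcc"] == 0.0

    def test_hand_computed_confusion(self):
        yt = ["positive"] * 10 + ["negative"] * 10
        yp = (["positive"] * 8 + ["negative"] * 2
              + ["positive"] * 2 + ["negative"] * 8)
        m = classification_metrics(yt, yp)
        assert m["mcc"] == pytest.approx(0.6)
        assert m["accuracy"] == pytest.approx(0.8)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (8, 2, 2, 8)

    def test_zero_denominator_warns(self):
        yt = ["positive", "negative"]
        yp = ["negative", "negative"]
        with pytest.warns(UserWarning, match="MCC denominator"):
            m = classification_metrics(yt, yp)
        assert m["mcc"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            classification_metrics(["positive"], ["positive", "negative"])

    def test_matches_sklearn_oracle_on_random_vectors(self):
        from sklearn.metrics import confusion_matrix, matthews_corrcoef

        rng = np.random.default_rng(3)
        for _ in range(100):
            yt = np.where(rng.random(50) < 0.7, "negative", "positive")
            yp = np.where(rng.random(50) < 0.6, "negative", "positive")
            m = classification_metrics(yt, yp)
            tn, fp, fn, tp = confusion_matrix(
                yt, yp, labels=["negative", "positive"]).ravel()
            assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (tp, fp, fn, tn)
            if len(set(yt)) == 2 and len(set(yp)) == 2:
                assert m["mcc"] == pytest.approx(matthews_corrcoef(yt, yp))


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        y = np.array([0.0, 1.0, 2.0])
        m = regression_metrics(y, y)
        assert m["rmse"] == 0.0 and m["nrmse"] == 0.0 and m["r2"] == 1.0

    def test_mean_predictor_identity(self):
        y = np.random.default_rng(0).normal(size=50)
        m = regression_metrics(y, np.full_like(y, y.mean()))
        assert m["nrmse"] == 1.0
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        m = regression_metrics([0.0, 2.0], [1.0, 1.0])
        assert m["rmse"] == 1.0 and m["nrmse"] == 1.0

    def test_degenerate_targets_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            regression_metrics([1.0, 1.0], [1.0, 2.0])


class TestErrorProfile:
    def test_no_errors_all_zero(self):
        y = ["negative", "positive"]
        prof = error_vs_strength_profile([-0.5, 0.5], y, y, bins=[-1, 0, 1])
        assert prof[["false_positives", "false_negatives"]].to_numpy().sum() == 0

    def test_single_false_negative_placement(self):
        prof = error_vs_strength_profile(
            [-0.05], ["positive"], ["negative"], bins=np.arange(-0.3, 0.31, 0.1))
        row = prof[(prof["bin_left"] < -0.05) & (prof["bin_right"] >= -0.05)]
        assert row["false_negatives"].sum() == 1
        assert prof["false_negatives"].sum() == 1

    def test_errors_concentrated_near_zero(self):
        rng = np.random.default_rng(4)
        strength = rng.uniform(-2, 2, 200)
        y_true = np.where(strength > 0, "positive", "negative")
        # predictions wrong only when |strength| < 0.2
        y_pred = np.where(np.abs(strength) < 0.2,
                          np.where(y_true == "positive", "negative", "positive"),
                          y_true)
        prof = error_vs_strength_profile(strength, y_true, y_pred,
                                         bins=np.arange(-2, 2.1, 0.5))
        outer = prof[(prof["bin_right"] <= -0.5) | (prof["bin_left"] >= 0.5)]
        assert outer[["false_positives", "false_negatives"]].to_numpy().sum() == 0


class TestAblation:
    def test_variant_feature_sets(self):
        cols = ["mono_affected", "mono_affecting", "metab_dist",
                "affected_phylo_pc1", "carbon_pc1"]
        assert _variant_columns(cols, "no_coculture") == cols
        assert _variant_columns(cols, "no_coculture_no_monoculture") == [
            "affected_phylo_pc1", "carbon_pc1"]
        assert _variant_columns(cols, "phylo_only") == ["affected_phylo_pc1"]

    def test_leakage_guard_raises(self):
        idx = pd.MultiIndex.from_tuples([("A", "B", "C1"), ("B", "D", "C2")])
        with pytest.raises(AssertionError, match="leakage"):
            _leakage_guard(idx, "A", "species")
        with pytest.raises(AssertionError, match="leakage"):
            _leakage_guard(idx, "C2", "carbon")
        _leakage_guard(idx, "Z", "species")  # clean index passes

    def test_null_nrmse_near_one_across_seeds(self, small_dataset):
        """Mean-predictor NRMSE sits near 1 up to train/test mean drift."""
        from pairfx.features import aligned_labels, assemble_features
        from pairfx.models import fit_null_model

        ds, _ = small_dataset
        X = assemble_features(ds)
        y = aligned_labels(ds, X)
        for seed in range(3):
            tr, te = split_train_test(ds.effects, 0.2, seed=seed)
            trk = pd.MultiIndex.from_frame(
                tr[["affected", "affecting", "carbon"]]).intersection(X.index)
            tek = pd.MultiIndex.from_frame(
                te[["affected", "affecting", "carbon"]]).intersection(X.index)
            null = fit_null_model(ModelSpec(family="null", task="strength"),
                                  X.loc[trk], y.loc[trk, "effect"].to_numpy())
            m = regression_metrics(y.loc[tek, "effect"],
                                   null.predict(X.loc[tek]))
            assert 0.9 <= m["nrmse"] <= 1.1

    def test_species_harness_structure(self, small_dataset):
        ds, _ = small_dataset
        spec = ModelSpec(family="gradient_boosted_trees", task="strength",
                         fixed_params=TINY_PARAMS, seed=0)
        res = loo_species_ablation(ds, spec, species_list=ds.species[:2])
        assert set(res["variant"]) >= {"no_coculture",
                                       "no_coculture_no_monoculture",
                                       "phylo_only", "copy", "null_model"}
        assert (res["metric"] == "nrmse").all()
        assert np.isfinite(res["value"]).all()
        per_unit = res.groupby("held_out_id")["variant"].nunique()
        assert (per_unit >= 5).all()

    def test_twin_copy_error_is_zero_on_conserved_data(self):
        ds = make_conserved_twin_dataset()
        keys = [k for k in ds.effect_lookup() if "T" in (k[0], k[1])]
        lookup = ds.effect_lookup()
        y_true = [lookup[k] for k in keys]
        y_pred = [phylo_copy_predict(ds, k, uncultured="T") for k in keys]
        m = regression_metrics(y_true, y_pred)
        assert m["nrmse"] == 0.0
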