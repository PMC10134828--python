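"""Splits, metrics, and leave-one-out partial-information ablations.

Sign models are scored by Matthews correlation (robust to the strong
negative-class imbalance of coculture screens); strength models by NRMSE,
the RMSE divided by the population standard deviation of the observed
effects in the test set, so that predicting the test mean scores ~1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .growth import NEGATIVE, POSITIVE, InteractionDataset
from .features import (
    FeatureOptions,
    aligned_labels,
    assemble_features,
    carbon_pcs,
)
from .models import (
    ModelSpec,
    TrainedModel,
    fit_null_model,
    metabolic_copy_predict,
    phylo_copy_predict,
    tune_and_train,
)

logger = logging.getLogger(__name__)

ABLATION_VARIANTS = ("full", "no_coculture", "no_coculture_no_monoculture",
                     "phylo_only", "copy", "null")


def split_train_test(
    effects: pd.DataFrame,
    test_frac: float = 0.2,
    seed: int = 0,
    stratify_by_sign: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random 80/20 split of effect records, stratified by sign by default."""
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    n_test = int(round(len(effects) * test_frac))
    if n_test < 1 or n_test >= len(effects):
        raise ValueError("split leaves an empty train or test set")
    strat = effects["sign"] if stratify_by_sign else None
    train, test = train_test_split(
        effects, test_size=test_frac, random_state=seed, stratify=strat
    )
    if stratify_by_sign and (
        train["sign"].nunique() < 2 or test["sign"].nunique() < 2
    ):
        raise ValueError("dataset too small to stratify both classes into both splits")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def classification_metrics(y_true, y_pred, scores=None) -> dict:
    """Confusion counts and derived rates for binary sign labels.

    Positive effects are the positive class.  MCC with a zero denominator
    is reported as 0 with a warning.  ROC-AUC is included only when
    classifier scores are provided.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between y_true and y_pred")
    tp = int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE)))
    tn = int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE)))
    fp = int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE)))
    fn = int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE)))
    n = len(y_true)

    def rate(num, den):
        return num / den if den > 0 else np.nan

    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting MCC = 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    out = {
        "task": "sign", "n": n,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": (tp + tn) / n,
        "mcc": float(mcc),
        "precision": rate(tp, tp + fp),
        "recall": rate(tp, tp + fn),
        "tpr": rate(tp, tp + fn),
        "tnr": rate(tn, tn + fp),
        "ppv": rate(tp, tp + fp),
        "npv": rate(tn, tn + fn),
    }
    if scores is not None:
        out["roc_auc"] = float(roc_auc_score((y_true == POSITIVE).astype(int), scores))
    return out


def regression_metrics(y_true, y_pred) -> dict:
    """RMSE, R^2 and NRMSE (RMSE / population SD of the observed effects)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between y_true and y_pred")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    sd = float(np.std(y_true))  # ddof=0: the mean predictor scores exactly 1
    if sd == 0:
        raise ValueError("degenerate test targets: zero standard deviation")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return {
        "task": "strength", "n": len(y_true),
        "rmse": rmse,
        "nrmse": rmse / sd,
        "r2": 1.0 - ss_res / ss_tot,
    }


def error_vs_strength_profile(
    y_true_strength, y_true_sign, y_pred_sign, bins
) -> pd.DataFrame:
    """False positive / false negative counts per bin of true effect strength.

    Sign-classification errors concentrate near zero effect strength; this
    histogram makes that error structure visible.
    """
    s = np.asarray(y_true_strength, dtype=float)
    yt, yp = np.asarray(y_true_sign), np.asarray(y_pred_sign)
    if not (len(s) == len(yt) == len(yp)):
        raise ValueError("input vectors must be aligned")
    bins = np.asarray(bins, dtype=float)
    fp = (yt == NEGATIVE) & (yp == POSITIVE)
    fn = (yt == POSITIVE) & (yp == NEGATIVE)
    fp_counts, _ = np.histogram(s[fp], bins=bins)
    fn_counts, _ = np.histogram(s[fn], bins=bins)
    return pd.DataFrame({
        "bin_left": bins[:-1], "bin_right": bins[1:],
        "false_positives": fp_counts, "false_negatives": fn_counts,
    })


def evaluate_model(model: TrainedModel, X: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Apply a trained model to a labeled feature table and score it."""
    if model.spec.task.endswith("sign"):
        pred = model.predict(X)
        scores = model.predict_scores(X)
        return classification_metrics(labels["sign"], pred, scores=scores)
    return regression_metrics(labels["effect"], model.predict(X))


# ---------------------------------------------------------------------------
# leave-one-out ablations

def _involving(index: pd.MultiIndex, species: str) -> np.ndarray:
    return np.array([
        species in (a, b) for a, b, _ in index
    ])


_MONO_COLS = ("mono_affected", "mono_affecting", "metab_dist")


def _variant_columns(columns: list[str], variant: str) -> list[str]:
    if variant == "no_coculture":
        return list(columns)
    if variant == "no_coculture_no_monoculture":
        return [c for c in columns if c not in _MONO_COLS]
    if variant == "phylo_only":
        return [c for c in columns if "phylo_pc" in c]
    raise ValueError(f"unknown trained variant {variant!r}")


def _metric_value(task: str, y_true_labels: pd.DataFrame, pred) -> tuple[str, float]:
    if task == "sign":
        m = classification_metrics(y_true_labels["sign"], pred)
        return "mcc", m["mcc"]
    m = regression_metrics(y_true_labels["effect"], pred)
    return "nrmse", m["nrmse"]


def _leakage_guard(train_index: pd.MultiIndex, held_out: str, axis: str) -> None:
    if axis == "species":
        bad = any(held_out in (a, b) for a, b, _ in train_index)
    else:
        bad = any(c == held_out for _, _, c in train_index)
    if bad:
        raise AssertionError(f"leakage: training rows reference held-out {held_out}")


def _fit_variant(spec: ModelSpec, X_tr, y_tr):
    if spec.task == "sign":
        y = y_tr["sign"].to_numpy()
    else:
        y = y_tr["effect"].to_numpy()
    return tune_and_train(spec, X_tr, y)


def _copy_predictions(dataset, test_index, axis, held_out, what):
    preds, keys = [], []
    for key in test_index:
        try:
            if axis == "species":
                v = phylo_copy_predict(dataset, key, uncultured=held_out, what=what)
            else:
                v = metabolic_copy_predict(dataset, key, excluded_carbon=held_out,
                                           what=what)
        except LookupError:
            continue
        preds.append(v)
        keys.append(key)
    return keys, preds


def loo_ablation(
    dataset: InteractionDataset,
    spec: ModelSpec,
    axis: str,
    held_out_ids: list[str] | None = None,
    options: FeatureOptions | None = None,
    test_frac: float = 0.2,
    global_model: TrainedModel | None = None,
) -> pd.DataFrame:
    """Partial-information harness for one axis (``species`` or ``carbon``).

    For every held-out unit, three feature-variant models are trained on all
    records not involving it and scored on the records that do:
    ``no_coculture`` (all features), ``no_coculture_no_monoculture`` (per-pair
    monoculture features removed), ``phylo_only``.  A copy baseline
    (phylogenetic copy for species, metabolic copy for carbons) and the null
    model are evaluated on the same test records, and the ordinary
    80/20-split model provides the ``full``-information reference.  For a
    held-out carbon, carbon PCs are refit without it and its own profile is
    embedded by projection, never by refit.

    Hyperparameters are reused from ``spec`` (pass ``fixed_params`` from a
    global tuning run to avoid re-tuning per held-out unit).
    """
    if axis not in ("species", "carbon"):
        raise ValueError("axis must be 'species' or 'carbon'")
    options = options or FeatureOptions()
    full_X = assemble_features(dataset, options)
    full_y = aligned_labels(dataset, full_X)
    ids = held_out_ids or (dataset.species if axis == "species" else dataset.carbons)

    # "full" reference: the ordinary split model, scored on each unit's
    # records inside the global test split
    if global_model is None:
        tr_idx, te_idx = _split_index(full_y, test_frac, spec.seed, spec.task)
        global_model = _fit_variant(spec, full_X.loc[tr_idx], full_y.loc[tr_idx])
    else:
        _, te_idx = _split_index(full_y, test_frac, spec.seed, spec.task)

    what = "sign" if spec.task == "sign" else "effect"
    rows = []
    for held in ids:
        if axis == "species":
            test_mask = _involving(full_X.index, held)
        else:
            test_mask = np.array([c == held for _, _, c in full_X.index])
        test_index = full_X.index[test_mask]
        if len(test_index) == 0:
            warnings.warn(f"held-out {held} has no records; skipped", stacklevel=2)
            continue
        train_index = full_X.index[~test_mask]
        _leakage_guard(train_index, held, axis)

        if axis == "carbon":
            # refit the carbon PC space without the held-out environment
            mono_tr = dataset.mono_yields.drop(columns=[held])
            _, projection = carbon_pcs(mono_tr, options.n_carbon_pcs)
            X_all = assemble_features(dataset, options, carbon_projection=projection)
        else:
            X_all = full_X

        y_te = full_y.loc[test_index]
        try:
            for variant in ("no_coculture", "no_coculture_no_monoculture", "phylo_only"):
                cols = _variant_columns(list(X_all.columns), variant)
                model = _fit_variant(spec, X_all.loc[train_index, cols],
                                     full_y.loc[train_index])
                pred = model.predict(X_all.loc[test_index, cols])
                metric, value = _metric_value(spec.task, y_te, pred)
                rows.append((held, variant, metric, value, len(test_index)))

            # copy baseline
            keys, preds = _copy_predictions(dataset, test_index, axis, held, what)
            if keys:
                metric, value = _metric_value(spec.task, full_y.loc[keys], preds)
                rows.append((held, "copy", metric, value, len(keys)))

            # null reference on the same test records
            null = fit_null_model(replace(spec, family="null"),
                                  full_X.loc[train_index],
                                  full_y.loc[train_index, "effect" if what == "effect"
                                             else "sign"].to_numpy())
            metric, value = _metric_value(spec.task, y_te,
                                          null.predict(full_X.loc[test_index]))
            rows.append((held, "null_model", metric, value, len(test_index)))

            # full-information reference
            te_unit = [k for k in te_idx if k in set(test_index)]
            if len(te_unit) >= 2:
                pred = global_model.predict(full_X.loc[te_unit])
                metric, value = _metric_value(spec.task, full_y.loc[te_unit], pred)
                rows.append((held, "full", metric, value, len(te_unit)))
        except ValueError as err:
            warnings.warn(f"held-out {held}: {err}; skipped", stacklevel=2)
            continue
        logger.info("ablation axis=%s held_out=%s done", axis, held)

    return pd.DataFrame(rows, columns=["held_out_id", "variant", "metric",
                                       "value", "n_test"])


def _split_index(labels: pd.DataFrame, test_frac: float, seed: int, task: str):
    strat = labels["sign"] if task == "sign" else None
    tr, te = train_test_split(labels.index, test_size=test_frac,
                              random_state=seed, stratify=strat)
    return list(tr), list(te)


def loo_species_ablation(dataset, spec, species_list=None, **kw) -> pd.DataFrame:
    return loo_ablation(dataset, spec, "species", species_list, **kw)


def loo_carbon_ablation(dataset, spec, carbon_list=None, **kw) -> pd.DataFrame:
    return loo_ablation(dataset, spec, "carbon", carbon_list, **kw)
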