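"""Interpretation analyses.

1. Shapley attributions of the tuned strength model (which features drive
   predictions, and in which direction) plus a beeswarm figure.
2. Copy-model error versus phylogenetic distance, with the Pearson
   correlation between the two.
3. Dependence between reciprocal effects (MIC), and the effect of adding
   the measured reciprocal effect as a feature.
4. Joint (multilabel) two-way prediction versus two independent one-way
   predictions.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from pairfx import growth
from pairfx.features import FeatureOptions, aligned_labels, assemble_features, read_features
from pairfx.evaluation import regression_metrics, split_train_test
from pairfx.interpretation import (
    attribute_predictions,
    copy_accuracy_vs_distance,
    plot_attribution_beeswarm,
    reciprocal_dependence,
)
from pairfx.models import ModelSpec, tune_and_train

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=ROOT / "results" / "dataset")
    ap.add_argument("--features", type=Path, default=ROOT / "results" / "features.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--budget", type=int, default=50)
    args = ap.parse_args()

    ds = growth.read_dataset(args.dataset)
    X = read_features(args.features)
    y = aligned_labels(ds, X)
    tr, te = split_train_test(ds.effects, 0.2, seed=args.seed)
    trk = pd.MultiIndex.from_frame(
        tr[["affected", "affecting", "carbon"]]).intersection(X.index)
    tek = pd.MultiIndex.from_frame(
        te[["affected", "affecting", "carbon"]]).intersection(X.index)

    spec = ModelSpec(family="gradient_boosted_trees", task="strength",
                     budget=args.budget, cv_folds=5, seed=args.seed)
    model = tune_and_train(spec, X.loc[trk], y.loc[trk, "effect"].to_numpy())

    # --- attributions
    rng = np.random.default_rng(args.seed)
    rows_idx = tek[rng.choice(len(tek), size=min(150, len(tek)), replace=False)]
    attr = attribute_predictions(model, X.loc[rows_idx], background=X.loc[trk],
                                 n_background=30, n_permutations=25,
                                 seed=args.seed)
    attr.values.to_csv(args.out / "attributions.csv", float_format="%.5g")
    plot_attribution_beeswarm(attr, X.loc[rows_idx],
                              args.out / "attribution_beeswarm.png")
    print("mean |attribution| ranking:")
    for name, v in attr.mean_abs.items():
        r = stats.pearsonr(X.loc[rows_idx, name], attr.values[name])[0]
        print(f"  {name:22s} {v:.4f}  (value-attribution r = {r:+.2f})")

    # --- copy error vs phylogenetic distance
    table, r, p = copy_accuracy_vs_distance(ds)
    table.to_csv(args.out / "copy_vs_distance.csv", index=False,
                 float_format="%.4f")
    print(f"\ncopy-model NRMSE vs phylogenetic distance: "
          f"Pearson r = {r:.2f} (p = {p:.2g}, n = {len(table)})")

    # --- reciprocal effects
    mic_v = reciprocal_dependence(ds.effects)
    print(f"reciprocal-effect MIC: {mic_v:.3f}")

    X_plus = assemble_features(ds, FeatureOptions(reciprocal_effect=True))
    common_tr = trk.intersection(X_plus.index)
    common_te = tek.intersection(X_plus.index)
    fixed = ModelSpec(family="gradient_boosted_trees", task="strength",
                      fixed_params=model.best_params, seed=args.seed)
    base = tune_and_train(fixed, X.loc[common_tr],
                          y.loc[common_tr, "effect"].to_numpy())
    plus = tune_and_train(fixed, X_plus.loc[common_tr],
                          y.loc[common_tr, "effect"].to_numpy())
    n_base = regression_metrics(y.loc[common_te, "effect"],
                                base.predict(X.loc[common_te]))["nrmse"]
    n_plus = regression_metrics(y.loc[common_te, "effect"],
                                plus.predict(X_plus.loc[common_te]))["nrmse"]
    print(f"NRMSE without/with reciprocal-effect feature: "
          f"{n_base:.3f} / {n_plus:.3f} (delta {n_plus - n_base:+.3f})")

    # --- joint two-way vs independent one-way prediction
    lookup = ds.effect_lookup()
    canon = [k for k in X.index if k[0] < k[1] and (k[1], k[0], k[2]) in lookup]
    y2 = np.array([[lookup[k], lookup[(k[1], k[0], k[2])]] for k in canon])
    pos = {k: i for i, k in enumerate(canon)}
    tr2 = [k for k in canon if k in set(trk)]
    te2 = [k for k in canon if k in set(tek)]
    joint_spec = ModelSpec(family="gradient_boosted_trees",
                           task="two_way_strength",
                           fixed_params=model.best_params, seed=args.seed)
    joint = tune_and_train(joint_spec, X.loc[tr2], y2[[pos[k] for k in tr2]])
    mirror = [(k[1], k[0], k[2]) for k in te2]
    pred_one = np.column_stack([model.predict(X.loc[te2]),
                                model.predict(X.loc[mirror])])
    y_te2 = y2[[pos[k] for k in te2]]
    j = regression_metrics(y_te2.ravel(), joint.predict(X.loc[te2]).ravel())["nrmse"]
    o = regression_metrics(y_te2.ravel(), pred_one.ravel())["nrmse"]
    print(f"two-way NRMSE, joint multilabel vs twice one-way: {j:.3f} vs {o:.3f}")


if __name__ == "__main__":
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        main()
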