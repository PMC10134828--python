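"""Train and evaluate sign and strength models against the naive baselines.

Gradient-boosted trees with seeded random hyperparameter search (budget 50,
5-fold CV) on an 80/20 sign-stratified split, compared with the null model
(most frequent sign / mean effect) and the two single-feature threshold
rules.  Also reports the false-positive / false-negative counts per bin of
true effect strength.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from pairfx import growth
from pairfx.features import aligned_labels, read_features
from pairfx.evaluation import (
    error_vs_strength_profile,
    evaluate_model,
    split_train_test,
)
from pairfx.models import ModelSpec, fit_null_model, fit_threshold_model, tune_and_train

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

    for task, ycol in (("sign", "sign"), ("strength", "effect")):
        spec = ModelSpec(family="gradient_boosted_trees", task=task,
                         budget=args.budget, cv_folds=5, seed=args.seed)
        model = tune_and_train(spec, X.loc[trk], y.loc[trk, ycol].to_numpy())
        rows = [dict(model="gradient_boosted_trees",
                     **evaluate_model(model, X.loc[tek], y.loc[tek]))]
        null = fit_null_model(ModelSpec(family="null", task=task),
                              X.loc[trk], y.loc[trk, ycol].to_numpy())
        rows.append(dict(model="null_model",
                         **evaluate_model(null, X.loc[tek], y.loc[tek])))
        if task == "sign":
            for feat in ("metab_dist", "mono_affected"):
                thr = fit_threshold_model(feat, X.loc[trk],
                                          y.loc[trk, "sign"].to_numpy())
                rows.append(dict(model=f"threshold_{feat}",
                                 **evaluate_model(thr, X.loc[tek], y.loc[tek])))
            profile = error_vs_strength_profile(
                y.loc[tek, "effect"], y.loc[tek, "sign"],
                model.predict(X.loc[tek]), bins=np.arange(-3, 3.01, 0.25))
            profile.to_csv(args.out / "error_vs_strength.csv", index=False)
            near = profile[(profile["bin_left"] >= -0.5)
                           & (profile["bin_right"] <= 0.5)]
            total_err = profile[["false_positives", "false_negatives"]].sum().sum()
            near_err = near[["false_positives", "false_negatives"]].sum().sum()
            print(f"sign errors within |effect| < 0.5: "
                  f"{near_err}/{total_err} ({near_err / total_err:.0%})")
        table = pd.DataFrame(rows)
        table.to_csv(args.out / f"metrics_{task}.csv", index=False,
                     float_format="%.4f")
        cols = (["model", "accuracy", "mcc", "precision", "recall"]
                if task == "sign" else ["model", "nrmse", "r2"])
        print(f"\n{task} models (test set, n={rows[0]['n']}):")
        print(table[cols].to_string(index=False, float_format="%.3f"))


if __name__ == "__main__":
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        main()
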