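"""End-to-end experiment orchestration from a single config.

A run goes: load or synthesize the screen -> replicate filter + log-ratio
effects -> feature table -> tuned model + naive baselines -> test-set
metrics -> optional leave-one-out ablations, attribution, copy-vs-distance
and reciprocal-dependence analyses.  Every output lands in the run
directory together with the resolved config, and the whole run is a pure
function of (config, seed): stage seeds are derived from the global seed
with a fixed counter scheme (SeedSequence spawn keys 0, 1, 2, ...).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth
from .features import FeatureOptions, aligned_labels, assemble_features
from .evaluation import (
    classification_metrics,
    evaluate_model,
    loo_ablation,
    regression_metrics,
    split_train_test,
)
from .interpretation import (
    attribute_predictions,
    copy_accuracy_vs_distance,
    reciprocal_dependence,
    reciprocal_pairs,
)
from .models import ModelSpec, fit_null_model, fit_threshold_model, tune_and_train
from .synth import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class ExperimentConfig:
    """Everything a run needs; serialized into the output directory."""

    seed: int = 0
    output_dir: str = "results/run"
    # data source: synthetic config dict, or paths to real inputs
    synthetic: dict | None = field(default_factory=dict)
    growth_csv: str | None = None
    phylo_path: str | None = None
    min_reps: int = 3

    tasks: tuple[str, ...] = ("sign", "strength")
    family: str = "gradient_boosted_trees"
    budget: int = 50
    cv_folds: int = 5
    test_frac: float = 0.2
    stratify: bool = True

    features: dict = field(default_factory=dict)
    ablation_axes: tuple[str, ...] = ()
    ablation_max_units: int | None = None

    attributions: bool = False
    attribution_rows: int = 150
    attribution_permutations: int = 25
    attribution_background: int = 30
    copy_vs_distance: bool = False
    reciprocal_mic: bool = False
    two_way: bool = False

    def validate(self) -> None:
        if self.synthetic is None and self.growth_csv is None:
            raise ValueError("config must give a synthetic block or input paths")
        for t in self.tasks:
            if t not in ("sign", "strength"):
                raise ValueError(f"unknown task {t!r}")
        for ax in self.ablation_axes:
            if ax not in ("species", "carbon"):
                raise ValueError(f"unknown ablation axis {ax!r}")

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = ExperimentConfig(**raw)
        cfg.tasks = tuple(cfg.tasks)
        cfg.ablation_axes = tuple(cfg.ablation_axes)
        return cfg

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["tasks"] = list(self.tasks)
        payload["ablation_axes"] = list(self.ablation_axes)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _stage_seed(global_seed: int, stage: int) -> int:
    return int(np.random.SeedSequence(entropy=global_seed,
                                      spawn_key=(stage,)).generate_state(1)[0] % (2 ** 31))


def load_data(config: ExperimentConfig):
    if config.growth_csv is not None:
        table = growth.read_growth_table(config.growth_csv)
        phylo = growth.read_phylo_distances(config.phylo_path)
        dataset = growth.build_dataset(table, phylo, min_reps=config.min_reps)
        return dataset, None
    syn = SyntheticConfig(**{**(config.synthetic or {}), "seed": _stage_seed(config.seed, 0)})
    return generate_dataset(syn)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute all configured stages; returns a summary dict (also on disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("pairfx")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed}
    try:
        config.to_yaml(out / "config_resolved.yaml")

        logger.info("stage: data")
        dataset, truth = load_data(config)
        growth.write_dataset(dataset, out)
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FMT)
        neg_frac = float((dataset.effects["sign"] == growth.NEGATIVE).mean())
        summary["n_effects"] = int(len(dataset.effects))
        summary["negative_fraction"] = neg_frac

        logger.info("stage: features")
        opts = FeatureOptions(**config.features)
        X = assemble_features(dataset, opts)
        y = aligned_labels(dataset, X)
        from .features import write_features

        write_features(X, out / "features.csv")

        split_seed = _stage_seed(config.seed, 1)
        tr_eff, te_eff = split_train_test(
            dataset.effects, config.test_frac, seed=split_seed,
            stratify_by_sign=config.stratify,
        )
        tr_keys = pd.MultiIndex.from_frame(tr_eff[["affected", "affecting", "carbon"]])
        te_keys = pd.MultiIndex.from_frame(te_eff[["affected", "affecting", "carbon"]])
        tr_keys = tr_keys.intersection(X.index)
        te_keys = te_keys.intersection(X.index)

        trained = {}
        for task in config.tasks:
            logger.info("stage: train %s", task)
            spec = ModelSpec(family=config.family, task=task, budget=config.budget,
                             cv_folds=config.cv_folds, seed=_stage_seed(config.seed, 2))
            ycol = "sign" if task == "sign" else "effect"
            model = tune_and_train(spec, X.loc[tr_keys], y.loc[tr_keys, ycol].to_numpy())
            trained[task] = model
            model.save(out / f"model_{task}.pkl")

            rows = [dict(model=config.family,
                         **evaluate_model(model, X.loc[te_keys], y.loc[te_keys]))]
            null = fit_null_model(ModelSpec(family="null", task=task),
                                  X.loc[tr_keys], y.loc[tr_keys, ycol].to_numpy())
            # "null" is a pandas NA token in CSVs; use an unambiguous label
            rows.append(dict(model="null_model",
                             **evaluate_model(null, X.loc[te_keys], y.loc[te_keys])))
            if task == "sign" and not opts.drop_monoculture_features:
                for feat in ("metab_dist", "mono_affected"):
                    thr = fit_threshold_model(feat, X.loc[tr_keys],
                                              y.loc[tr_keys, "sign"].to_numpy())
                    rows.append(dict(model=f"threshold_{feat}",
                                     **evaluate_model(thr, X.loc[te_keys],
                                                      y.loc[te_keys])))
            mdf = pd.DataFrame(rows)
            mdf.to_csv(out / f"metrics_{task}.csv", index=False,
                       float_format=_FLOAT_FMT)
            key = "mcc" if task == "sign" else "nrmse"
            summary[f"{task}_{key}"] = float(mdf.iloc[0][key])

        if config.two_way and "strength" in config.tasks:
            logger.info("stage: two-way")
            summary["two_way"] = _two_way_comparison(config, dataset, X, y,
                                                     tr_keys, te_keys, out)

        for axis in config.ablation_axes:
            logger.info("stage: ablation %s", axis)
            task = "strength" if "strength" in config.tasks else "sign"
            base = trained[task]
            spec = ModelSpec(family=config.family, task=task,
                             fixed_params=base.best_params,
                             cv_folds=config.cv_folds,
                             seed=_stage_seed(config.seed, 3))
            units = dataset.species if axis == "species" else dataset.carbons
            if config.ablation_max_units:
                units = units[: config.ablation_max_units]
            res = loo_ablation(dataset, spec, axis, held_out_ids=units,
                               options=opts, test_frac=config.test_frac,
                               global_model=base)
            res.to_csv(out / f"ablation_{axis}.csv", index=False,
                       float_format=_FLOAT_FMT)
            med = res.groupby("variant")["value"].median()
            summary[f"ablation_{axis}_medians"] = {k: float(v)
                                                   for k, v in med.items()}

        if config.attributions and "strength" in trained:
            logger.info("stage: attributions")
            rng = np.random.default_rng(_stage_seed(config.seed, 4))
            take = min(config.attribution_rows, len(te_keys))
            rows_idx = te_keys[rng.choice(len(te_keys), size=take, replace=False)]
            attr = attribute_predictions(
                trained["strength"], X.loc[rows_idx], method="sampling",
                background=X.loc[tr_keys],
                n_background=config.attribution_background,
                n_permutations=config.attribution_permutations,
                seed=_stage_seed(config.seed, 5),
            )
            attr.values.to_csv(out / "attributions.csv", float_format=_FLOAT_FMT)
            summary["top_feature"] = attr.ranking()[0]
            summary["attribution_base_value"] = attr.base_value

        if config.copy_vs_distance:
            logger.info("stage: copy vs distance")
            table, r, pval = copy_accuracy_vs_distance(dataset, metric="nrmse")
            table.to_csv(out / "copy_vs_distance.csv", index=False,
                         float_format=_FLOAT_FMT)
            summary["copy_error_distance_pearson_r"] = r
            summary["copy_error_distance_pearson_p"] = pval

        if config.reciprocal_mic:
            logger.info("stage: reciprocal MIC")
            pairs = reciprocal_pairs(dataset.effects)
            summary["n_reciprocal_pairs"] = int(len(pairs))
            summary["reciprocal_mic"] = float(
                reciprocal_dependence(dataset.effects))

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        logger.info("run complete")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def _two_way_comparison(config, dataset, X, y, tr_keys, te_keys, out) -> dict:
    """Multilabel joint prediction versus two independent one-way models.

    Rows are canonical (affected < affecting); the joint target is
    [effect on affected, effect on affecting].
    """
    lookup = dataset.effect_lookup()
    canon = [k for k in X.index if k[0] < k[1] and (k[1], k[0], k[2]) in lookup]
    Xc = X.loc[canon]
    y2 = np.array([[lookup[k], lookup[(k[1], k[0], k[2])]] for k in canon])
    tr = [k for k in canon if k in set(tr_keys)]
    te = [k for k in canon if k in set(te_keys)]
    pos = {k: i for i, k in enumerate(canon)}

    spec = ModelSpec(family=config.family, task="two_way_strength",
                     budget=config.budget, cv_folds=config.cv_folds,
                     seed=_stage_seed(config.seed, 6))
    joint = tune_and_train(spec, Xc.loc[tr], y2[[pos[k] for k in tr]])
    pred_joint = joint.predict(Xc.loc[te])

    one_spec = ModelSpec(family=config.family, task="strength",
                         budget=config.budget, cv_folds=config.cv_folds,
                         seed=_stage_seed(config.seed, 6))
    one = tune_and_train(one_spec, X.loc[tr_keys],
                         y.loc[tr_keys, "effect"].to_numpy())
    mirror = [(k[1], k[0], k[2]) for k in te]
    pred_one = np.column_stack([
        one.predict(X.loc[te]), one.predict(X.loc[mirror])
    ])

    y_te = y2[[pos[k] for k in te]]
    res = {
        "joint_nrmse": regression_metrics(y_te.ravel(), pred_joint.ravel())["nrmse"],
        "oneway_nrmse": regression_metrics(y_te.ravel(), pred_one.ravel())["nrmse"],
        "n_test_pairs": len(te),
    }
    pd.DataFrame([res]).to_csv(out / "metrics_two_way.csv", index=False,
                               float_format=_FLOAT_FMT)
    return res
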