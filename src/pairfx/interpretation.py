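"""Model interpretation: Shapley attributions, copy-model accuracy versus
phylogenetic distance, and the dependence between reciprocal effects.

Attributions are interventional Shapley values: the value of a feature
coalition is the model's expected output when coalition features take the
explained row's values and the rest are drawn from a background sample of
training rows.  Exact enumeration is available for small feature counts;
otherwise seeded permutation sampling is used.  Both satisfy local accuracy
(base value + attributions = prediction) by construction, which is checked.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .growth import NEGATIVE, POSITIVE, InteractionDataset
from .mic import mic
from .models import TrainedModel


@dataclass
class AttributionTable:
    """Per-row, per-feature attributions in model-output units."""

    values: pd.DataFrame   # rows x features
    base_value: float

    @property
    def mean_abs(self) -> pd.Series:
        """Feature importance: mean absolute attribution, descending."""
        return self.values.abs().mean(axis=0).sort_values(ascending=False)

    def ranking(self) -> list[str]:
        return list(self.mean_abs.index)


def _predict_fn(model):
    if isinstance(model, TrainedModel):
        est = model.estimator
        if model.spec.task.endswith("sign"):
            if not hasattr(est, "predict_proba"):
                raise ValueError("sign model without scores cannot be attributed")
            classes = list(est.classes_)
            pos = classes.index(POSITIVE)
            return lambda arr: est.predict_proba(arr)[:, pos]
        return lambda arr: np.asarray(est.predict(arr), dtype=float)
    return lambda arr: np.asarray(model(arr), dtype=float)


def attribute_predictions(
    model,
    features: pd.DataFrame,
    method: str = "sampling",
    background: pd.DataFrame | None = None,
    n_background: int = 100,
    n_permutations: int = 30,
    seed: int = 0,
    tol: float = 1e-6,
) -> AttributionTable:
    """Shapley attributions for every row of ``features``.

    ``method="exact_small"`` enumerates all feature coalitions (<= 12
    features); ``method="sampling"`` averages marginal contributions over
    seeded random feature orderings.  ``background`` defaults to a seeded
    sample of the supplied rows.
    """
    f = _predict_fn(model)
    X = features.to_numpy(dtype=float)
    cols = list(features.columns)
    p = len(cols)
    rng = np.random.default_rng(seed)
    if background is None:
        take = min(n_background, len(features))
        bg = X[rng.choice(len(features), size=take, replace=False)]
    else:
        if list(background.columns) != cols:
            raise ValueError("background columns must match the feature table")
        bg = background.to_numpy(dtype=float)
        if len(bg) > n_background:
            bg = bg[rng.choice(len(bg), size=n_background, replace=False)]
    base = float(np.mean(f(bg)))

    if method == "exact_small":
        if p > 12:
            raise ValueError("exact_small supports at most 12 features")
        phi = _exact_shapley(f, X, bg, p)
    elif method == "sampling":
        phi = _sampling_shapley(f, X, bg, p, n_permutations, rng)
    else:
        raise ValueError(f"unknown method {method!r}")

    pred = f(X)
    resid = np.abs(base + phi.sum(axis=1) - pred)
    if (resid > max(tol, 1e-6)).any():
        raise RuntimeError(
            f"local accuracy violated: max |base + sum(phi) - f(x)| = {resid.max():.3g} "
            f"(tol {tol:g}, method {method})"
        )
    return AttributionTable(
        values=pd.DataFrame(phi, index=features.index, columns=cols),
        base_value=base,
    )


def _exact_shapley(f, X, bg, p) -> np.ndarray:
    n, n_bg = X.shape[0], bg.shape[0]
    masks = list(itertools.product((0, 1), repeat=p))
    # coalition values, batched into a single predict call per row
    phi = np.zeros((n, p))
    fact = [math.factorial(k) for k in range(p + 1)]
    weights = {
        s: fact[s] * fact[p - s - 1] / fact[p] for s in range(p)
    }
    for i in range(n):
        stacked = np.empty((len(masks) * n_bg, p))
        for m_idx, mask in enumerate(masks):
            block = bg.copy()
            sel = np.asarray(mask, dtype=bool)
            block[:, sel] = X[i, sel]
            stacked[m_idx * n_bg:(m_idx + 1) * n_bg] = block
        vals = f(stacked).reshape(len(masks), n_bg).mean(axis=1)
        value = dict(zip(masks, vals))
        for j in range(p):
            for mask in masks:
                if mask[j] == 1:
                    continue
                with_j = tuple(1 if k == j else m for k, m in enumerate(mask))
                s = sum(mask)
                phi[i, j] += weights[s] * (value[with_j] - value[mask])
    return phi


def _sampling_shapley(f, X, bg, p, n_permutations, rng) -> np.ndarray:
    """Permutation-sampling Shapley, vectorized across rows and background.

    Each permutation's marginal contributions telescope to
    f(x) - E[f(background)], so the averaged attributions satisfy local
    accuracy exactly.
    """
    n, n_bg = X.shape[0], bg.shape[0]
    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        current = np.repeat(bg[None, :, :], n, axis=0)  # (n, n_bg, p)
        prev_vals = f(current.reshape(n * n_bg, p)).reshape(n, n_bg).mean(axis=1)
        for j in order:
            current[:, :, j] = X[:, j][:, None]
            vals = f(current.reshape(n * n_bg, p)).reshape(n, n_bg).mean(axis=1)
            phi[:, j] += vals - prev_vals
            prev_vals = vals
    return phi / n_permutations


# ---------------------------------------------------------------------------
# copy-model accuracy versus phylogenetic distance

def copy_accuracy_vs_distance(
    dataset: InteractionDataset,
    metric: str = "nrmse",
    min_records: int = 3,
) -> tuple[pd.DataFrame, float, float]:
    """Score every (target, source) species pair under pure copying.

    All of the target's recorded effects (in either direction) are predicted
    by substituting the source species into the record key and copying its
    recorded value in the same carbon with the same partner.  Returns one
    row per ordered pair (metric value, phylogenetic distance, same-group
    flag, coverage) plus the Pearson correlation between the metric and
    distance.  For error metrics (NRMSE) conserved interactions make the
    correlation positive.
    """
    if metric not in ("nrmse", "accuracy", "mcc"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(dataset.species) < 3:
        raise ValueError("need at least 3 species")
    lookup = dataset.effect_lookup()
    d = dataset.phylo_dist
    offdiag = d.to_numpy()[~np.eye(len(d), dtype=bool)]
    family_cut = float(np.median(offdiag))
    rows = []
    for target in dataset.species:
        keys = [k for k in lookup if target in (k[0], k[1])]
        for source in dataset.species:
            if source == target:
                continue
            y_true, y_copy = [], []
            for key in keys:
                sub = tuple(source if x == target else x for x in key)
                if sub[0] == sub[1] or sub not in lookup:
                    continue
                y_true.append(lookup[key])
                y_copy.append(lookup[sub])
            if len(y_true) < min_records:
                warnings.warn(
                    f"copy pair ({target}, {source}): only {len(y_true)} "
                    "matching records; skipped", stacklevel=2)
                continue
            y_true, y_copy = np.asarray(y_true), np.asarray(y_copy)
            if metric == "nrmse":
                sd = np.std(y_true)
                if sd == 0:
                    continue
                value = float(np.sqrt(np.mean((y_true - y_copy) ** 2)) / sd)
            else:
                st = np.where(y_true > 0, POSITIVE, NEGATIVE)
                sc = np.where(y_copy > 0, POSITIVE, NEGATIVE)
                if metric == "accuracy":
                    value = float(np.mean(st == sc))
                else:
                    from .evaluation import classification_metrics

                    value = classification_metrics(st, sc)["mcc"]
            dist = float(d.at[target, source])
            rows.append((target, source, dist, dist <= family_cut,
                         value, len(y_true)))
    table = pd.DataFrame(rows, columns=["target", "source", "distance",
                                        "same_group", "value", "n"])
    r, pval = sstats.pearsonr(table["value"], table["distance"])
    return table, float(r), float(pval)


# ---------------------------------------------------------------------------
# reciprocal-effect dependence

def reciprocal_pairs(effects: pd.DataFrame) -> pd.DataFrame:
    """Paired reciprocal effects: one row per unordered pair x carbon with
    both directions measured."""
    lookup = {
        (r.affected, r.affecting, r.carbon): r.effect
        for r in effects.itertuples(index=False)
    }
    rows = []
    for (a, b, c), e_ab in lookup.items():
        if a < b and (b, a, c) in lookup:
            rows.append((a, b, c, e_ab, lookup[(b, a, c)]))
    return pd.DataFrame(rows, columns=["species_a", "species_b", "carbon",
                                       "effect_on_a", "effect_on_b"])


def reciprocal_dependence(
    effects: pd.DataFrame, method: str = "approx", max_n: int = 2000,
    **mic_kwargs
) -> float:
    """MIC between the two directions of each pair's effects.

    Weakly dependent reciprocal effects (MIC near 0) mean that knowing how
    A affects B says little about how B affects A.  Screens larger than
    ``max_n`` pairs are subsampled deterministically (the MIC grid budget
    grows as n^0.6 and dominates runtime).
    """
    pairs = reciprocal_pairs(effects)
    if method == "approx" and len(pairs) < 25:
        raise ValueError("need at least 25 reciprocal pairs")
    if len(pairs) > max_n:
        keep = np.random.default_rng(0).choice(len(pairs), size=max_n,
                                               replace=False)
        pairs = pairs.iloc[np.sort(keep)]
    x = pairs["effect_on_a"].to_numpy()
    y = pairs["effect_on_b"].to_numpy()
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("constant reciprocal effects; MIC is 0", stacklevel=2)
        return 0.0
    return mic(x, y, method=method, **mic_kwargs)


# ---------------------------------------------------------------------------
# plotting

def plot_attribution_beeswarm(attr: AttributionTable, features: pd.DataFrame,
                              path, top: int = 10) -> None:
    """Value-colored attribution scatter (beeswarm-style), top features."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = attr.ranking()[:top]
    fig, ax = plt.subplots(figsize=(7, 0.6 * len(ranked) + 1.5))
    rng = np.random.default_rng(0)
    for i, col in enumerate(reversed(ranked)):
        vals = attr.values[col].to_numpy()
        feat = features[col].to_numpy(dtype=float)
        fr = feat.argsort().argsort() / max(len(feat) - 1, 1)
        jitter = rng.normal(0, 0.08, size=len(vals))
        sc = ax.scatter(vals, np.full(len(vals), i) + jitter, c=fr,
                        cmap="coolwarm", s=8, alpha=0.7)
    ax.set_yticks(range(len(ranked)))
    ax.set_yticklabels(list(reversed(ranked)))
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("attribution (model output units)")
    fig.colorbar(sc, ax=ax, label="feature value (rank-scaled)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
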