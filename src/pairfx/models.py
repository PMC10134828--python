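"""Model families with a uniform train/predict contract.

ML families (gradient-boosted trees, random forest, k-nearest neighbors,
linear) are tuned by seeded random hyperparameter search with k-fold
cross-validation, scored by Matthews correlation (sign task) or RMSE
(strength / two-way task), then refit on the full training set.

Naive baselines:

- null: most frequent sign / mean effect of the training set;
- threshold: single-feature decision rule, threshold and inequality
  direction chosen to maximize training accuracy;
- phylogenetic copy: return the recorded effect of the phylogenetically
  closest species with data, same partner and carbon;
- metabolic copy: same, with carbons ranked by Euclidean distance between
  their metabolic profiles.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import KFold, ParameterSampler, StratifiedKFold
from sklearn.multioutput import MultiOutputClassifier, MultiOutputRegressor
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier, XGBRegressor

from .growth import NEGATIVE, POSITIVE, InteractionDataset
from .features import metabolic_distance_matrix

ML_FAMILIES = ("gradient_boosted_trees", "random_forest", "k_nearest_neighbors", "linear")
NAIVE_FAMILIES = ("null", "threshold", "phylo_copy", "metabolic_copy")
TASKS = ("sign", "strength", "two_way_sign", "two_way_strength")


def default_param_space(family: str, task: str) -> dict[str, Any]:
    """Default hyperparameter ranges per family (user-overridable)."""
    if family == "gradient_boosted_trees":
        return {
            "n_estimators": stats.randint(20, 150),
            "max_depth": stats.randint(2, 7),
            "learning_rate": stats.loguniform(0.03, 0.4),
            "subsample": stats.uniform(0.6, 0.4),
            "colsample_bytree": stats.uniform(0.6, 0.4),
            "reg_lambda": stats.loguniform(0.1, 10.0),
        }
    if family == "random_forest":
        return {
            "n_estimators": stats.randint(50, 300),
            "max_depth": stats.randint(2, 12),
            "max_features": stats.uniform(0.3, 0.7),
        }
    if family == "k_nearest_neighbors":
        return {
            "est__n_neighbors": stats.randint(1, 40),
            "est__weights": ["uniform", "distance"],
        }
    if family == "linear":
        if task.endswith("sign"):
            return {"est__C": stats.loguniform(1e-3, 1e3)}
        return {}
    raise ValueError(f"unknown ML family {family!r}")


@dataclass
class ModelSpec:
    """What to train: family, task, search space and budget."""

    family: str
    task: str
    param_space: dict[str, Any] | None = None
    budget: int = 2500
    cv_folds: int = 5
    seed: int = 0
    #: for the threshold family: which feature column to threshold on
    feature: str | None = None
    #: skip search and use exactly these hyperparameters
    fixed_params: dict[str, Any] | None = None

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.family not in ML_FAMILIES + NAIVE_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainedModel:
    """A fitted model plus everything needed to apply it safely."""

    spec: ModelSpec
    estimator: Any
    schema: list[str]
    best_params: dict[str, Any] = field(default_factory=dict)
    cv_score: float | None = None
    train_summary: dict[str, Any] = field(default_factory=dict)

    def _check_schema(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.schema:
            raise ValueError(
                f"feature schema mismatch: model trained on {self.schema}, "
                f"got {list(X.columns)}"
            )
        return X.to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame):
        arr = self._check_schema(X)
        pred = self.estimator.predict(arr)
        return np.asarray(pred)

    def predict_scores(self, X: pd.DataFrame):
        """Positive-class scores for ROC analysis (None if unavailable)."""
        arr = self._check_schema(X)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(arr)
            classes = list(est.classes_)
            return proba[:, classes.index(POSITIVE)]
        return None

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format_version": 1, "model": self}, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        return payload["model"]


def _make_estimator(family: str, task: str, params: dict[str, Any], seed: int):
    classify = task.endswith("sign")
    multi = task.startswith("two_way")
    if family == "gradient_boosted_trees":
        cls = XGBClassifier if classify else XGBRegressor
        est = cls(random_state=seed, n_jobs=1, tree_method="hist",
                  verbosity=0, **params)
        if classify:
            est = _LabelWrapped(est)
    elif family == "random_forest":
        cls = RandomForestClassifier if classify else RandomForestRegressor
        est = cls(random_state=seed, n_jobs=1, **params)
    elif family == "k_nearest_neighbors":
        cls = KNeighborsClassifier if classify else KNeighborsRegressor
        inner = {k.removeprefix("est__"): v for k, v in params.items()}
        est = Pipeline([("scale", StandardScaler()), ("est", cls(**inner))])
    elif family == "linear":
        if classify:
            inner = {k.removeprefix("est__"): v for k, v in params.items()}
            est = Pipeline([
                ("scale", StandardScaler()),
                ("est", LogisticRegression(max_iter=2000, random_state=seed, **inner)),
            ])
        else:
            est = LinearRegression()
    else:
        raise ValueError(f"unknown ML family {family!r}")
    if multi:
        est = (MultiOutputClassifier(est) if classify else MultiOutputRegressor(est))
    return est


class _LabelWrapped:
    """String-label adapter around XGBoost classifiers."""

    def __init__(self, est):
        self.est = est
        self.classes_ = None

    def get_params(self, deep=True):
        return {"est": self.est}

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self.est.fit(X, codes)
        return self

    def predict(self, X):
        return self.classes_[self.est.predict(X)]

    def predict_proba(self, X):
        return self.est.predict_proba(X)


def _cv_score(family, task, params, X, y, folds, seed) -> float:
    """Mean CV score; higher is better (RMSE is negated)."""
    classify = task.endswith("sign")
    if classify and not task.startswith("two_way"):
        splitter = StratifiedKFold(folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    else:
        splitter = KFold(folds, shuffle=True, random_state=seed)
        split = splitter.split(X)
    scores = []
    for tr, te in split:
        est = _make_estimator(family, task, params, seed)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        if classify:
            yt, yp = np.asarray(y[te]).ravel(), np.asarray(pred).ravel()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores.append(matthews_corrcoef(yt, yp))
        else:
            scores.append(-float(np.sqrt(np.mean((np.asarray(y[te]) - pred) ** 2))))
    return float(np.mean(scores))


def tune_and_train(spec: ModelSpec, X: pd.DataFrame, y) -> TrainedModel:
    """Random search + k-fold CV, then refit the winner on all data.

    Sign models are selected by highest mean Matthews correlation,
    strength models by lowest mean RMSE.  Fully seeded: the same spec and
    data always select the same hyperparameters.
    """
    if spec.family == "null":
        return fit_null_model(spec, X, y)
    if spec.family == "threshold":
        return fit_threshold_model(spec.feature, X, y, spec=spec)
    if spec.family not in ML_FAMILIES:
        raise ValueError(f"{spec.family!r} has no tune_and_train path")
    schema = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y)
    if spec.task == "sign" and len(np.unique(ya)) < 2:
        raise ValueError("degenerate labels: single-class sign training set")

    if spec.fixed_params is not None:
        best_params, best_score = dict(spec.fixed_params), None
    else:
        space = spec.param_space or default_param_space(spec.family, spec.task)
        if space:
            sampler = ParameterSampler(space, n_iter=spec.budget, random_state=spec.seed)
            candidates = list(sampler)
        else:
            candidates = [{}]
        best_params, best_score = None, -np.inf
        for params in candidates:
            score = _cv_score(spec.family, spec.task, params, Xa, ya,
                              spec.cv_folds, spec.seed)
            if score > best_score:
                best_params, best_score = params, score
    est = _make_estimator(spec.family, spec.task, best_params, spec.seed)
    est.fit(Xa, ya)
    summary = _train_summary(spec.task, ya)
    return TrainedModel(spec=spec, estimator=est, schema=schema,
                        best_params=best_params, cv_score=best_score,
                        train_summary=summary)


def _train_summary(task: str, y) -> dict[str, Any]:
    y = np.asarray(y)
    if task.endswith("sign"):
        vals, counts = np.unique(y.ravel(), return_counts=True)
        return {"most_frequent_sign": vals[np.argmax(counts)],
                "negative_fraction": float(np.mean(y.ravel() == NEGATIVE))}
    return {"mean_effect": float(np.mean(y))}


# ---------------------------------------------------------------------------
# naive models

def fit_null_model(spec: ModelSpec, X: pd.DataFrame, y) -> TrainedModel:
    """Most frequent sign / mean effect of the training set."""
    ya = np.asarray(y)
    if spec.task.endswith("sign"):
        est = DummyClassifier(strategy="most_frequent")
    else:
        est = DummyRegressor(strategy="mean")
    est.fit(X.to_numpy(dtype=float), ya)
    return TrainedModel(spec=spec, estimator=est, schema=list(X.columns),
                        train_summary=_train_summary(spec.task, ya))


class _ThresholdEstimator:
    def __init__(self, column_index, threshold, high_sign):
        self.column_index = column_index
        self.threshold = threshold
        self.high_sign = high_sign  # sign predicted when feature >= threshold
        self.low_sign = POSITIVE if high_sign == NEGATIVE else NEGATIVE

    def predict(self, X):
        x = np.asarray(X)[:, self.column_index]
        return np.where(x >= self.threshold, self.high_sign, self.low_sign)


def fit_threshold_model(
    feature_name: str, X: pd.DataFrame, y, spec: ModelSpec | None = None
) -> TrainedModel:
    """Single-feature decision rule maximizing training accuracy.

    Candidate thresholds are midpoints between consecutive sorted distinct
    feature values plus +/- infinity; both inequality directions are
    searched.  Ties prefer the smaller threshold, then the
    ">= predicts negative" direction.  A constant feature degrades to the
    null sign behavior with a warning.
    """
    if feature_name not in X.columns:
        raise KeyError(f"feature {feature_name!r} not in table")
    spec = spec or ModelSpec(family="threshold", task="sign", feature=feature_name)
    x = X[feature_name].to_numpy(dtype=float)
    ya = np.asarray(y)
    uniq = np.unique(x)
    if uniq.size < 2:
        warnings.warn(f"constant feature {feature_name!r}: threshold model "
                      "degrades to the null sign model", stacklevel=2)
        return fit_null_model(spec, X, y)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    col = list(X.columns).index(feature_name)
    best = None  # (accuracy, threshold, direction_rank)
    for t in candidates:
        for rank, high_sign in enumerate((NEGATIVE, POSITIVE)):
            est = _ThresholdEstimator(col, t, high_sign)
            acc = float(np.mean(est.predict(X.to_numpy(dtype=float)) == ya))
            key = (-acc, t, rank)
            if best is None or key < best[0]:
                best = (key, est, acc)
    _, est, acc = best
    return TrainedModel(
        spec=spec, estimator=est, schema=list(X.columns),
        best_params={"threshold": est.threshold, "high_sign": est.high_sign,
                     "feature": feature_name},
        cv_score=acc, train_summary=_train_summary("sign", ya),
    )


# ---------------------------------------------------------------------------
# copy models

def _copy_from_ranked(
    lookup: dict, candidates: list, substitute: callable
) -> tuple[float, Any]:
    for cand in candidates:
        key = substitute(cand)
        if key in lookup and key[0] != key[1]:
            return lookup[key], cand
    raise LookupError("no copyable interaction")


def phylo_copy_predict(
    dataset: InteractionDataset,
    query: tuple[str, str, str],
    uncultured: str,
    excluded_species: list[str] | None = None,
    what: str = "effect",
):
    """Copy the record of the phylogenetically closest species with data.

    ``uncultured`` is the species with no usable data (it may sit in either
    slot of the query).  Candidate species are ranked by distance to it
    (ties broken lexicographically); if the closest lacks the matching
    record the next-closest is used.  Raises LookupError when no candidate
    has any matching record.
    """
    affected, affecting, carbon = query
    if uncultured not in (affected, affecting):
        raise ValueError("query does not involve the uncultured species")
    excluded = set(excluded_species or []) | {uncultured}
    d = dataset.phylo_dist
    ranked = sorted(
        (s for s in d.index if s not in excluded),
        key=lambda s: (float(d.at[uncultured, s]), s),
    )
    lookup = dataset.effect_lookup()

    def substitute(cand):
        return tuple(cand if x == uncultured else x for x in (affected, affecting, carbon))

    value, _ = _copy_from_ranked(lookup, ranked, substitute)
    return (POSITIVE if value > 0 else NEGATIVE) if what == "sign" else value


def metabolic_copy_predict(
    dataset: InteractionDataset,
    query: tuple[str, str, str],
    excluded_carbon: str,
    what: str = "effect",
):
    """Copy the same pair's record from the metabolically closest carbon.

    Carbons are ranked by Euclidean distance between their metabolic
    profiles (all species' monoculture yields; the held-out carbon's own
    monoculture profile is assumed available).  Falls back down the ranking
    when records are missing.
    """
    affected, affecting, carbon = query
    if carbon != excluded_carbon:
        raise ValueError("query is not in the excluded carbon")
    prof = dataset.imputed_profiles()
    target = prof[carbon].to_numpy(dtype=float)
    dists = {
        c: float(np.linalg.norm(prof[c].to_numpy(dtype=float) - target))
        for c in prof.columns if c != carbon
    }
    ranked = sorted(dists, key=lambda c: (dists[c], c))
    lookup = dataset.effect_lookup()
    value, _ = _copy_from_ranked(lookup, ranked,
                                 lambda cand: (affected, affecting, cand))
    return (POSITIVE if value > 0 else NEGATIVE) if what == "sign" else value
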