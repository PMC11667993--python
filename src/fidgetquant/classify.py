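"""Feature-discriminability harness: repeated nested cross-validation.

Each movement feature is evaluated on its own as a 1-D classifier input —
the question is which single feature carries the most diagnostic signal, so
features compete head to head rather than jointly. Six model families are
benchmarked, each tuned over a small fixed hyperparameter grid:

==================  =====================================================
family              grid
==================  =====================================================
svm_rbf             gamma {50, 100, 300, 500}; C {0.001, 0.01, 0.1, 1}
random_forest       n_estimators {1, 5, 10, 20, 30, 50}
decision_tree_cart  max_depth {1, 2}
knn                 n_neighbors {1, 2}
adaboost_cart       n_estimators {1, 5, 10, 20, 30, 50} (CART stumps)
xgboost_cart        max_depth {1, 2}; learning_rate {0.1, 0.2};
                    n_estimators {1, 5, 10, 20}
==================  =====================================================

Protocol: an outer stratified 10-fold split estimates generalisation; within
each outer training set an inner stratified 5-fold grid search picks the
hyperparameters maximising inner accuracy; the winner is refit on the full
outer-training set and scored on the held-out fold. The whole procedure is
repeated 10 times with reshuffled folds, giving 100 train/test pairs, and
each metric's spread across the 100 iterations is summarised by the
standard error of the mean, SEM = sigma / sqrt(n).

Outer folds are stratified: with ~equal class sizes, unstratified 10-fold
splitting risks single-class test folds in which sensitivity or specificity
is undefined. Scale-sensitive families (SVM, KNN) get per-fold train-set
standardisation; tree ensembles are scale-invariant and are fit raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError

METRICS = ("accuracy", "sensitivity", "specificity", "auc")

FAMILIES = (
    "svm_rbf",
    "random_forest",
    "decision_tree_cart",
    "knn",
    "adaboost_cart",
    "xgboost_cart",
)

#: Hyperparameter grids, as published; override per-call if needed. The SVM
#: ranges (large gamma, small C) are implemented as printed even though the
#: magnitudes are unusual for standardised 1-D inputs.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm_rbf": {"gamma": [50, 100, 300, 500], "C": [0.001, 0.01, 0.1, 1]},
    "random_forest": {"n_estimators": [1, 5, 10, 20, 30, 50]},
    "decision_tree_cart": {"max_depth": [1, 2]},
    "knn": {"n_neighbors": [1, 2]},
    "adaboost_cart": {"n_estimators": [1, 5, 10, 20, 30, 50]},
    "xgboost_cart": {
        "max_depth": [1, 2],
        "learning_rate": [0.1, 0.2],
        "n_estimators": [1, 5, 10, 20],
    },
}

_SCALED_FAMILIES = frozenset({"svm_rbf", "knn"})


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameter search grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )
        if not self.grid:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation layout (defaults: 10 x 10 outer, 5 inner)."""

    outer_folds: int = 10
    inner_folds: int = 5
    repeats: int = 10
    seed: int = 0
    positive_class: str = "pos"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2 or self.repeats < 1:
            raise ConfigurationError("invalid CV layout")

    @property
    def n_iterations(self) -> int:
        return self.repeats * self.outer_folds


def _base_estimator(family: str, seed: int):
    if family == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "decision_tree_cart":
        return DecisionTreeClassifier(random_state=seed)
    if family == "knn":
        return KNeighborsClassifier()
    if family == "adaboost_cart":
        # scikit-learn's default AdaBoost weak learner is a CART stump
        return AdaBoostClassifier(random_state=seed)
    if family == "xgboost_cart":
        from xgboost import XGBClassifier

        return XGBClassifier(
            eval_metric="logloss", n_jobs=1, verbosity=0, random_state=seed
        )
    raise ConfigurationError(f"unknown family {family!r}")


def build_estimator(spec: ModelSpec, seed: int = 0):
    """Estimator + grid ready for GridSearchCV; scaled families get a
    StandardScaler fitted inside each training fold (no leakage)."""
    est = _base_estimator(spec.family, seed)
    if spec.family in _SCALED_FAMILIES:
        pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
        grid = {f"clf__{k}": v for k, v in spec.grid.items()}
        return pipe, grid
    return est, spec.grid


def _scores_for(estimator, x: np.ndarray) -> np.ndarray:
    """Continuous decision values for the positive class."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(x)[:, 1]
    return estimator.decision_function(x)


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
    positive_class=1,
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and ROC AUC for one test fold.

    Sensitivity/specificity are undefined when the fold lacks the relevant
    class, and AUC when it lacks either class; those come back as NaN and
    are excluded from downstream means.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ConfigurationError("y_true and y_pred must be aligned")
    pos = y_true == positive_class
    neg = ~pos
    tp = int(np.sum(pos & (y_pred == positive_class)))
    tn = int(np.sum(neg & (y_pred != positive_class)))
    out = {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": tp / pos.sum() if pos.any() else np.nan,
        "specificity": tn / neg.sum() if neg.any() else np.nan,
    }
    if scores is not None and pos.any() and neg.any():
        out["auc"] = float(roc_auc_score(pos.astype(int), scores))
    else:
        out["auc"] = np.nan
    return out


def nested_cv(
    x: np.ndarray,
    y: np.ndarray,
    model: ModelSpec | str,
    cv: CVConfig = CVConfig(),
) -> pd.DataFrame:
    """Repeated nested CV of one model family on one feature.

    ``x`` is the feature (1-D for the standard single-feature evaluation;
    a 2-D array is accepted for multi-feature use). Returns one row per
    outer train/test pair — ``repeats x outer_folds`` rows (100 at the
    defaults) — with columns repeat, fold, best_params and the four metrics.
    """
    if isinstance(model, str):
        model = ModelSpec(model)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ConfigurationError(f"need exactly 2 classes, got {classes.tolist()}")
    if cv.positive_class not in classes:
        raise ConfigurationError(
            f"positive_class {cv.positive_class!r} absent from labels {classes.tolist()}"
        )
    y_bin = (y == cv.positive_class).astype(int)
    if float(np.ptp(x)) == 0.0:
        import warnings

        warnings.warn("feature is constant; models will be degenerate", stacklevel=2)

    rows = []
    for rep in range(cv.repeats):
        outer = StratifiedKFold(
            n_splits=cv.outer_folds, shuffle=True, random_state=cv.seed + rep
        )
        for fold, (tr, te) in enumerate(outer.split(x, y_bin)):
            est, grid = build_estimator(model, seed=cv.seed)
            inner = StratifiedKFold(
                n_splits=cv.inner_folds,
                shuffle=True,
                random_state=(cv.seed * 1009 + rep * 101 + fold) % (2**31),
            )
            search = GridSearchCV(
                est, grid, scoring="accuracy", cv=inner, refit=True, n_jobs=1
            )
            search.fit(x[tr], y_bin[tr])
            y_pred = search.predict(x[te])
            scores = _scores_for(search.best_estimator_, x[te])
            metrics = compute_metrics(y_bin[te], y_pred, scores, positive_class=1)
            rows.append(
                {
                    "model": model.family,
                    "repeat": rep,
                    "fold": fold,
                    "iteration": rep * cv.outer_folds + fold + 1,
                    "best_params": str(search.best_params_),
                    **metrics,
                }
            )
    return pd.DataFrame(rows)


def evaluate_features(
    features: pd.DataFrame,
    feature_cols: list[str],
    families: list[str] | None = None,
    cv: CVConfig = CVConfig(),
    grids: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Run nested CV for every (model family x feature x rate) combination.

    ``features`` is a tidy table with a ``label`` column, optionally a
    ``rate_d`` column, and one column per feature. Returns the concatenated
    per-iteration performance records.
    """
    families = list(families or FAMILIES)
    rates = sorted(features["rate_d"].unique()) if "rate_d" in features else [None]
    frames = []
    for rate in rates:
        sub = features if rate is None else features[features["rate_d"] == rate]
        y = sub["label"].to_numpy()
        for col in feature_cols:
            x = sub[col].to_numpy()
            for fam in families:
                spec = ModelSpec(fam, (grids or {}).get(fam, {}))
                perf = nested_cv(x, y, spec, cv)
                perf.insert(1, "feature", col)
                if rate is not None:
                    perf.insert(2, "rate_d", rate)
                frames.append(perf)
    return pd.concat(frames, ignore_index=True)


def sem(values: np.ndarray) -> float:
    """Standard error of the mean, sigma / sqrt(n), over CV iterations.

    sigma is the sample standard deviation; NaN entries (undefined fold
    metrics) are excluded from both sigma and n.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ConfigurationError("SEM needs at least 2 values")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def summarize(perf: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SEM of each metric per (model, feature[, rate]) cell.

    NaN fold metrics (single-class folds) are excluded from the means and
    counted in ``<metric>_n_missing``.
    """
    keys = [k for k in ("model", "feature", "rate_d") if k in perf.columns]
    rows = []
    for vals, grp in perf.groupby(keys):
        row = dict(zip(keys, vals if isinstance(vals, tuple) else (vals,)))
        for metric in METRICS:
            v = grp[metric].to_numpy(dtype=float)
            ok = v[~np.isnan(v)]
            row[f"{metric}_mean"] = ok.mean() if ok.size else np.nan
            row[f"{metric}_sem"] = sem(v) if ok.size >= 2 else np.nan
            row[f"{metric}_n_missing"] = int(np.isnan(v).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def _rank_within(means: pd.Series) -> pd.Series:
    """Rank 1 = best (largest mean); ties share the average rank."""
    return pd.Series(
        stats.rankdata(-means.to_numpy(), method="average"), index=means.index
    )


def _check_complete(perf: pd.DataFrame) -> None:
    cells = perf.groupby(["model", "feature"]).size()
    models = perf["model"].unique()
    feats = perf["feature"].unique()
    missing = [
        (m, f) for m in models for f in feats if (m, f) not in cells.index
    ]
    if missing:
        raise ConfigurationError(f"missing (model, feature) cells: {missing}")


def rank_features(perf: pd.DataFrame) -> pd.DataFrame:
    """Average rank of each feature per metric, across model families.

    Within each model family the features are ranked by mean metric
    (1 = best); those ranks are then averaged over families, one column per
    metric. The feature with average rank closest to 1 discriminates best.
    """
    if perf["feature"].nunique() < 2:
        raise ConfigurationError("ranking needs at least 2 features")
    _check_complete(perf)
    out = {}
    for metric in METRICS:
        means = perf.groupby(["model", "feature"])[metric].mean().unstack()
        ranks = means.apply(_rank_within, axis=1)
        out[metric] = ranks.mean(axis=0)
    return pd.DataFrame(out)


def rank_models(perf: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Rank the model families on one feature, per metric (1 = best)."""
    sub = perf[perf["feature"] == feature]
    if sub.empty:
        raise ConfigurationError(f"no records for feature {feature!r}")
    out = {}
    for metric in METRICS:
        means = sub.groupby("model")[metric].mean()
        out[metric] = _rank_within(means)
    return pd.DataFrame(out)
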