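"""Class-weighted, cross-validated glioma-grade classifier selection.

A fixed menu of scikit-learn classifiers stands in for an evolutionary
AutoML search: each menu entry is evaluated over a seeded random sample
of its documented hyperparameter ranges with stratified k-fold
cross-validation, and the winner is chosen by mean CV accuracy (ties
broken by mean F1, then lexicographic name).  Published winning
configurations are exposed as named presets so those exact pipelines
remain runnable.

The positive class for precision/recall is HGG (recall = sensitivity
for high-grade disease detection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "ModelSpec",
    "ModelReport",
    "class_weights",
    "evaluate",
    "rank_auc",
    "cross_validate",
    "model_search",
    "build_estimator",
    "MODEL_MENU",
    "PRESETS",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = "HGG"
NEGATIVE_CLASS = "LGG"

#: Classifier menu mirroring the AutoML search space: tree ensembles,
#: linear models, a distance-based and a probabilistic classifier.
MODEL_MENU: tuple[str, ...] = (
    "gradient_boosting",
    "random_forest",
    "sgd",
    "logistic_regression",
    "svm",
    "knn",
    "mlp",
    "bernoulli_nb",
)

#: Models whose fit() accepts sample_weight (class weighting route for
#: estimators without a class_weight parameter).
_SAMPLE_WEIGHT_MODELS = {"gradient_boosting", "bernoulli_nb"}
_CLASS_WEIGHT_MODELS = {"random_forest", "sgd", "logistic_regression", "svm"}


@dataclass(frozen=True)
class ModelSpec:
    """A menu entry: classifier name + hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    class_weighted: bool = True

    def __post_init__(self) -> None:
        if self.name not in MODEL_MENU:
            raise ValueError(f"unknown classifier {self.name!r}; menu: {MODEL_MENU}")


@dataclass
class ModelReport:
    """Per-fold and mean CV metrics plus pooled out-of-fold results."""

    spec: ModelSpec
    fold_metrics: pd.DataFrame
    mean_metrics: dict[str, float]
    pooled_metrics: dict[str, float]
    confusion: np.ndarray  # rows/cols ordered (LGG, HGG)
    roc_points: np.ndarray  # (fpr, tpr) pairs from pooled scores
    k: int
    cv_seed: int


def class_weights(y) -> dict[str, float]:
    """Balanced weights w(c) = n / (2 * n_c); minority class weighs more."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n = y.size
    return {str(c): n / (2.0 * int(nc)) for c, nc in zip(classes, counts)}


def rank_auc(y_true, y_score, positive_class: str = POSITIVE_CLASS) -> float:
    """AUC as the Mann-Whitney rank statistic with tie-averaging."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    pos = y_true == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(y_score)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(y_true, y_pred, y_score=None, positive_class: str = POSITIVE_CLASS) -> dict:
    """Accuracy/precision/recall/F1 (+AUC), HGG-positive, with the 2x2
    confusion matrix ordered (LGG, HGG).

    Precision with no positive predictions is reported as 0 with a
    warning rather than NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    labels = [NEGATIVE_CLASS, POSITIVE_CLASS]
    cm = sk_confusion_matrix(y_true, y_pred, labels=labels)
    tn, fp, fn, tp = cm.ravel()
    accuracy = (tp + tn) / cm.sum()
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    out = {
        "accuracy": float(accuracy),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "confusion": cm,
    }
    if y_score is not None:
        if not np.all(np.isfinite(np.asarray(y_score, dtype=np.float64))):
            raise ValueError("scores must be finite")
        out["auc"] = rank_auc(y_true, y_score, positive_class)
    return out


def build_estimator(spec: ModelSpec, weights: dict[str, float] | None = None):
    """Instantiate the sklearn estimator for a menu entry.

    ``weights`` (class -> weight) is attached via the estimator's
    class_weight parameter where supported; gradient boosting and
    naive Bayes get it at fit time through sample weights; KNN and MLP
    have no weighting mechanism (documented limitation).
    """
    hp = dict(spec.hyperparameters)
    cw = weights if (spec.class_weighted and weights is not None) else None
    name = spec.name
    if name == "gradient_boosting":
        return GradientBoostingClassifier(**hp)
    if name == "random_forest":
        return RandomForestClassifier(class_weight=cw, **hp)
    if name == "sgd":
        return SGDClassifier(class_weight=cw, **hp)
    if name == "logistic_regression":
        return LogisticRegression(class_weight=cw, max_iter=2000, **hp)
    if name == "svm":
        return SVC(class_weight=cw, **hp)
    if name == "knn":
        return KNeighborsClassifier(**hp)
    if name == "mlp":
        return MLPClassifier(**hp)
    if name == "bernoulli_nb":
        return BernoulliNB(**hp)
    raise ValueError(f"unknown classifier {name!r}")  # pragma: no cover


def _scores_from(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        pos_idx = list(model.classes_).index(POSITIVE_CLASS)
        return proba[:, pos_idx]
    margin = model.decision_function(X)
    # decision_function sign refers to classes_[1]
    return margin if model.classes_[1] == POSITIVE_CLASS else -margin


def _roc_points(y_true, y_score) -> np.ndarray:
    order = np.argsort(-np.asarray(y_score))
    y = (np.asarray(y_true)[order] == POSITIVE_CLASS).astype(int)
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return np.column_stack([fpr, tpr])


def cross_validate(X, y, spec: ModelSpec, k: int = 10, seed: int = 0) -> ModelReport:
    """Stratified k-fold CV with class-weighted training.

    k is reduced (with a warning) when the minority class has fewer than
    k members.  Reports unweighted fold-mean metrics and, separately,
    metrics pooled over the out-of-fold predictions; the pooled confusion
    matrix rows sum to the true class counts.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    min_count = int(counts.min())
    if min_count < k:
        warnings.warn(f"minority class has {min_count} members; reducing k from {k}")
        k = max(2, min_count)
    weights = class_weights(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    fold_rows = []
    oof_pred = np.empty(y.shape, dtype=object)
    oof_score = np.zeros(y.shape, dtype=np.float64)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = build_estimator(spec, weights)
        if spec.class_weighted and spec.name in _SAMPLE_WEIGHT_MODELS:
            sw = np.array([weights[str(c)] for c in y[tr]])
            model.fit(X[tr], y[tr], sample_weight=sw)
        else:
            model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        score = _scores_from(model, X[te])
        oof_pred[te] = pred
        oof_score[te] = score
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = evaluate(y[te], pred, score if len(np.unique(y[te])) > 1 else None)
        fold_rows.append(
            {"fold": fold, "accuracy": m["accuracy"], "precision": m["precision"],
             "recall": m["recall"], "f1": m["f1"], "auc": m.get("auc", np.nan)}
        )

    fold_metrics = pd.DataFrame(fold_rows)
    mean_metrics = {
        c: float(np.nanmean(fold_metrics[c])) for c in ("accuracy", "precision", "recall", "f1", "auc")
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = evaluate(y, oof_pred.astype(str), oof_score)
    pooled_metrics = {kk: vv for kk, vv in pooled.items() if kk != "confusion"}
    return ModelReport(
        spec=spec,
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
        pooled_metrics={k2: float(v2) for k2, v2 in pooled_metrics.items()},
        confusion=pooled["confusion"],
        roc_points=_roc_points(y, oof_score),
        k=k,
        cv_seed=seed,
    )


# ---------------------------------------------------------------------------
# Hyperparameter sampling and model search
# ---------------------------------------------------------------------------


def _sample_hyperparameters(name: str, rng: np.random.Generator) -> dict:
    """One random draw from each model's documented parameter ranges."""
    if name == "gradient_boosting":
        return {
            "learning_rate": float(rng.choice([0.01, 0.1, 0.5])),
            "max_depth": int(rng.integers(2, 9)),
            "n_estimators": 100,
            "subsample": float(rng.uniform(0.5, 1.0)),
            "min_samples_leaf": int(rng.integers(1, 15)),
            "min_samples_split": int(rng.integers(2, 21)),
            "random_state": int(rng.integers(0, 2**31 - 1)),
        }
    if name == "random_forest":
        return {
            "n_estimators": 100,
            "max_features": float(rng.uniform(0.1, 1.0)),
            "min_samples_leaf": int(rng.integers(1, 15)),
            "random_state": int(rng.integers(0, 2**31 - 1)),
        }
    if name == "sgd":
        return {
            "alpha": float(rng.choice([1e-4, 1e-3, 1e-2])),
            "penalty": str(rng.choice(["l2", "elasticnet"])),
            "l1_ratio": float(rng.choice([0.25, 0.5, 0.75])),
            "learning_rate": str(rng.choice(["optimal", "invscaling", "constant"])),
            "eta0": float(rng.choice([0.01, 0.1])),
            "power_t": float(rng.choice([0.1, 0.5])),
            "random_state": int(rng.integers(0, 2**31 - 1)),
        }
    if name == "logistic_regression":
        return {"C": float(rng.choice([0.01, 0.1, 1.0, 10.0])),
                "random_state": int(rng.integers(0, 2**31 - 1))}
    if name == "svm":
        return {
            "C": float(rng.choice([0.1, 1.0, 10.0])),
            "kernel": str(rng.choice(["linear", "rbf"])),
            "random_state": int(rng.integers(0, 2**31 - 1)),
        }
    if name == "knn":
        return {"n_neighbors": int(rng.choice([3, 5, 11, 21, 33, 39])),
                "p": int(rng.choice([1, 2])),
                "weights": str(rng.choice(["uniform", "distance"]))}
    if name == "mlp":
        return {
            "alpha": float(rng.choice([1e-4, 1e-3])),
            "learning_rate_init": float(rng.choice([0.001, 0.01, 0.1])),
            "max_iter": 500,
            "random_state": int(rng.integers(0, 2**31 - 1)),
        }
    if name == "bernoulli_nb":
        return {"alpha": float(rng.choice([0.01, 1.0, 10.0, 100.0]))}
    raise ValueError(f"unknown classifier {name!r}")  # pragma: no cover


def model_search(
    X,
    y,
    menu: tuple[str, ...] = MODEL_MENU,
    budget: int = 16,
    seed: int = 0,
    k: int = 10,
) -> tuple[ModelSpec, ModelReport]:
    """Deterministic random search over the fixed classifier menu.

    Each menu entry receives at least one sampled configuration; the
    remaining budget is distributed round-robin.  Winner = highest mean
    CV accuracy, ties broken by mean F1 then lexicographic name.
    """
    if len(menu) == 0:
        raise ValueError("empty menu")
    if budget < len(menu):
        raise ValueError(f"budget {budget} < menu size {len(menu)}")
    rng = np.random.default_rng(seed)
    candidates: list[ModelSpec] = []
    i = 0
    while len(candidates) < budget:
        name = menu[i % len(menu)]
        candidates.append(ModelSpec(name, _sample_hyperparameters(name, rng)))
        i += 1
    best: tuple | None = None
    for spec in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cross_validate(X, y, spec, k=k, seed=seed)
        acc = report.mean_metrics["accuracy"]
        f1 = report.mean_metrics["f1"]
        better = best is None or (acc, f1) > (best[0], best[1]) or (
            (acc, f1) == (best[0], best[1]) and spec.name < best[2]
        )
        if better:
            best = (acc, f1, spec.name, spec, report)
    return best[3], best[4]


#: Published winning configurations, runnable by name.  The T1Gd+T2 row
#: of the source search was a stacked pipeline and is not part of the
#: fixed menu.
PRESETS: dict[str, ModelSpec] = {
    "paper_flair_gb": ModelSpec("gradient_boosting", {
        "learning_rate": 0.01, "max_depth": 8, "max_features": 1.0,
        "min_samples_leaf": 11, "min_samples_split": 14,
        "n_estimators": 100, "subsample": 0.6501, "random_state": 0}),
    "paper_t1_gb": ModelSpec("gradient_boosting", {
        "learning_rate": 0.5, "max_depth": 2, "max_features": 0.1,
        "min_samples_leaf": 4, "min_samples_split": 20,
        "n_estimators": 100, "subsample": 0.55, "random_state": 0}),
    "paper_t1gd_bnb": ModelSpec("bernoulli_nb", {"alpha": 100.0, "fit_prior": False}),
    "paper_t2_sgd": ModelSpec("sgd", {
        "alpha": 0.01, "eta0": 0.1, "fit_intercept": False, "l1_ratio": 0.25,
        "learning_rate": "constant", "penalty": "elasticnet", "power_t": 10.0,
        "random_state": 0}),
    "paper_t1_flair_mlp": ModelSpec("mlp", {
        "alpha": 0.0001, "learning_rate_init": 0.1, "max_iter": 500, "random_state": 0}),
    "paper_t1gd_flair_sgd": ModelSpec("sgd", {
        "alpha": 0.001, "eta0": 0.01, "fit_intercept": True, "l1_ratio": 0.25,
        "learning_rate": "invscaling", "penalty": "elasticnet", "power_t": 0.1,
        "random_state": 0}),
    "paper_t1gd_t1_gb": ModelSpec("gradient_boosting", {
        "learning_rate": 0.1, "max_depth": 3, "max_features": 0.95,
        "min_samples_leaf": 9, "min_samples_split": 13,
        "n_estimators": 100, "subsample": 0.7, "random_state": 0}),
    "paper_t2_flair_knn": ModelSpec("knn", {
        "n_neighbors": 39, "p": 1, "weights": "uniform"}),
    "paper_t2_t1_mlp": ModelSpec("mlp", {
        "alpha": 0.0001, "learning_rate_init": 0.1, "max_iter": 500, "random_state": 0}),
}
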