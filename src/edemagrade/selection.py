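"""MinMax scaling and all-relevant (Boruta) feature selection.

The Boruta selector compares each real feature's gradient-boosted-tree
importance against the maximum importance among "shadow" features
(per-iteration random permutations of every column).  A feature beating
the shadow maximum scores a hit; accumulated hits are tested against a
Binomial(n_iterations, 1/2) null with a Bonferroni-corrected two-sided
test, moving features to confirmed or rejected.  Features still
undecided at ``max_iter`` are tentative.

``BorutaSelector`` follows the scikit-learn estimator contract (fit /
transform / get_support, fitted attributes with trailing underscores)
and composes with sklearn pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

__all__ = ["minmax_scale", "apply_minmax", "BorutaSelector", "SelectionResult", "boruta_select"]


def minmax_scale(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescale every feature column to [0, 1]; return (scaled, bounds).

    Constant columns map to 0 (with a warning).  ``bounds`` has rows
    ``min``/``max`` per feature so the identical transform can be applied
    to held-out rows via :func:`apply_minmax`.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 subjects to scale")
    values = table.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) scaled to 0 "
            f"(e.g. {table.columns[constant][0]!r})"
        )
    safe = np.where(constant, 1.0, span)
    scaled = (values - lo) / safe
    scaled[:, constant] = 0.0
    bounds = pd.DataFrame([lo, hi], index=["min", "max"], columns=table.columns)
    return pd.DataFrame(scaled, index=table.index, columns=table.columns), bounds


def apply_minmax(table: pd.DataFrame, bounds: pd.DataFrame) -> pd.DataFrame:
    """Apply stored (min, max) bounds to new rows (clipping not applied)."""
    lo = bounds.loc["min", table.columns].to_numpy()
    hi = bounds.loc["max", table.columns].to_numpy()
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = (table.to_numpy(dtype=np.float64) - lo) / safe
    scaled[:, span == 0] = 0.0
    return pd.DataFrame(scaled, index=table.index, columns=table.columns)


@dataclass
class SelectionResult:
    """Outcome of a Boruta run: a disjoint partition of the features."""

    confirmed: list[str]
    tentative: list[str]
    rejected: list[str]
    history: pd.DataFrame
    n_iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "confirmed": self.confirmed,
            "tentative": self.tentative,
            "rejected": self.rejected,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


class BorutaSelector(SelectorMixin, BaseEstimator):
    """All-relevant feature selection with shadow features.

    Parameters
    ----------
    max_iter : int
        Maximum number of shadow iterations (must be >= 5).
    alpha : float
        Significance level of the two-sided binomial hit test,
        Bonferroni-corrected within each iteration's undecided set.
    n_estimators : int
        Trees per XGBoost importance model.
    importance : {"gain", "permutation"}
        Importance measure; total gain by default.
    keep_tentative : bool
        Whether ``transform`` keeps still-undecided features.
    random_state : int
        Master seed; each iteration's shadow permutation uses its own
        child RNG stream.
    """

    def __init__(
        self,
        max_iter: int = 100,
        alpha: float = 0.05,
        n_estimators: int = 80,
        importance: str = "gain",
        keep_tentative: bool = False,
        random_state: int = 0,
    ):
        self.max_iter = max_iter
        self.alpha = alpha
        self.n_estimators = n_estimators
        self.importance = importance
        self.keep_tentative = keep_tentative
        self.random_state = random_state

    def _importances(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # Shallow, row- and column-subsampled trees keep real and shadow
        # importances exchangeable under the null: a greedy full-feature
        # fit would let the luckiest spuriously-correlated column beat
        # the freshly permuted shadow maximum almost every iteration.
        model = XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=2,
            subsample=0.7,
            colsample_bytree=0.15,
            tree_method="hist",
            importance_type="total_gain",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
            verbosity=0,
        )
        model.fit(X, y)
        if self.importance == "permutation":
            from sklearn.inspection import permutation_importance

            r = permutation_importance(
                model, X, y, n_repeats=5,
                random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
            )
            return r.importances_mean
        booster = model.get_booster()
        scores = booster.get_score(importance_type="total_gain")
        imp = np.zeros(X.shape[1])
        for key, val in scores.items():
            imp[int(key[1:])] = val
        return imp

    def fit(self, X, y):
        """Run the iterative shadow-feature procedure."""
        if self.max_iter < 5:
            raise ValueError("max_iter must be >= 5")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.importance not in ("gain", "permutation"):
            raise ValueError(f"unknown importance {self.importance!r}")
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=np.float64)
        else:
            Xv = np.asarray(X, dtype=np.float64)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        if Xv.ndim != 2:
            raise ValueError("X must be 2D")
        if not np.all(np.isfinite(Xv)):
            raise ValueError("X contains missing or non-finite values")
        yv = np.asarray(y)
        classes = np.unique(yv)
        if len(classes) < 2:
            raise ValueError("y must contain both classes")
        y_enc = (yv == classes[-1]).astype(int)

        n_features = Xv.shape[1]
        master = np.random.SeedSequence(self.random_state)
        streams = master.spawn(self.max_iter)

        status = np.zeros(n_features, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
        hits = np.zeros(n_features, dtype=int)
        trials = 0
        history_rows = []

        for it in range(self.max_iter):
            undecided = status == 0
            if not undecided.any():
                break
            rng = np.random.default_rng(streams[it])
            shadows = Xv.copy()
            for col in range(n_features):
                shadows[:, col] = rng.permutation(shadows[:, col])
            imp = self._importances(np.hstack([Xv, shadows]), y_enc, rng)
            real_imp = imp[:n_features]
            shadow_max = float(imp[n_features:].max())
            hits += (real_imp > shadow_max).astype(int)
            trials += 1

            n_undecided = int(undecided.sum())
            corrected = self.alpha / n_undecided
            # two-sided binomial test on accumulated hits, p = 1/2
            p_confirm = stats.binom.sf(hits - 1, trials, 0.5)  # P(H >= hits)
            p_reject = stats.binom.cdf(hits, trials, 0.5)      # P(H <= hits)
            newly_confirmed = undecided & (p_confirm < corrected)
            newly_rejected = undecided & (p_reject < corrected)
            status[newly_confirmed] = 1
            status[newly_rejected] = -1

            history_rows.append(
                {
                    "iteration": it + 1,
                    "shadow_max": shadow_max,
                    "n_confirmed": int((status == 1).sum()),
                    "n_rejected": int((status == -1).sum()),
                    "n_undecided": int((status == 0).sum()),
                    **{f"imp_{names[k]}": real_imp[k] for k in range(n_features)},
                }
            )

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = n_features
        self.classes_ = classes
        self.confirmed_ = [names[k] for k in range(n_features) if status[k] == 1]
        self.rejected_ = [names[k] for k in range(n_features) if status[k] == -1]
        self.tentative_ = [names[k] for k in range(n_features) if status[k] == 0]
        self.hits_ = hits
        self.n_iterations_ = trials
        self.history_ = pd.DataFrame(history_rows)
        keep = status == 1
        if self.keep_tentative:
            keep = keep | (status == 0)
        self.support_ = keep
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def result(self) -> SelectionResult:
        """The run's outcome as a :class:`SelectionResult`."""
        check_is_fitted(self, "support_")
        return SelectionResult(
            confirmed=list(self.confirmed_),
            tentative=list(self.tentative_),
            rejected=list(self.rejected_),
            history=self.history_,
            n_iterations=self.n_iterations_,
            seed=self.random_state,
        )


def boruta_select(
    X: pd.DataFrame,
    y,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> SelectionResult:
    """Functional wrapper over :class:`BorutaSelector`."""
    sel = BorutaSelector(max_iter=max_iter, alpha=alpha, random_state=seed, **kwargs)
    sel.fit(X, y)
    return sel.result()
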