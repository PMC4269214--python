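"""Feature-set reduction and per-user sequential forward selection.

Two consecutive steps shrink the feature battery before modeling:

1. correlation reduction, pooled over all users: of every pair with
   |Pearson r| above the threshold (and a significant p-value) the feature
   with the larger mean absolute correlation to the remaining features is
   dropped, until no flagged pair remains;
2. sequential forward selection, per user: starting from the empty set,
   repeatedly add the feature that maximises stratified k-fold CV accuracy
   of the stress logit, stopping when the best addition no longer improves
   on the current accuracy. The accuracy gain at addition is the feature's
   importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .model import DegenerateFitWarning, StressLogit
from .types import ValidationError

__all__ = [
    "CorrelationReport",
    "correlation_reduce",
    "SelectionResult",
    "sequential_forward_select",
    "cv_accuracy",
]


@dataclass
class CorrelationReport:
    """Outcome of the pooled correlation reduction."""

    pairs: list[tuple[str, str, float, float]]  # (a, b, r, p) for all pairs
    kept: list[str]
    dropped: list[str]

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "kept": self.kept,
            "dropped": self.dropped,
        }


def correlation_reduce(
    feature_table: pd.DataFrame,
    r_threshold: float = 0.8,
    p_threshold: float = 0.01,
) -> CorrelationReport:
    """Greedily drop one feature of every highly correlated pair.

    Pearson r and its two-sided p-value are computed on pairwise-complete
    rows. While a pair with |r| >= r_threshold and p < p_threshold remains
    among the kept features, the member with the larger mean absolute
    correlation to all other kept features is dropped (ties: the one later
    in column order). Constant features have undefined correlations and are
    kept with a warning. Deterministic, and idempotent by construction.
    """
    if not 0 < r_threshold < 1 or not 0 < p_threshold < 1:
        raise ValidationError("thresholds must lie in (0, 1)")
    features = list(feature_table.columns)
    n_complete = feature_table.dropna().shape[0]
    if n_complete < 3 and feature_table.shape[0] < 3:
        raise ValidationError("need at least 3 rows")

    r = pd.DataFrame(np.eye(len(features)), index=features, columns=features)
    p = pd.DataFrame(np.zeros((len(features), len(features))), index=features, columns=features)
    pairs: list[tuple[str, str, float, float]] = []
    for i, a in enumerate(features):
        for b in features[i + 1 :]:
            sub = feature_table[[a, b]].dropna()
            if sub.shape[0] < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                rv, pv = np.nan, np.nan
                if sub.shape[0] >= 3:
                    warnings.warn(
                        f"constant feature in pair ({a}, {b}); correlation undefined",
                        stacklevel=2,
                    )
            else:
                rv, pv = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
            pairs.append((a, b, float(rv), float(pv)))

    kept = list(features)
    dropped: list[str] = []
    while True:
        flagged = [
            (a, b)
            for i, a in enumerate(kept)
            for b in kept[i + 1 :]
            if np.isfinite(r.loc[a, b])
            and abs(r.loc[a, b]) >= r_threshold
            and p.loc[a, b] < p_threshold
        ]
        if not flagged:
            break
        candidates = sorted({f for pair in flagged for f in pair}, key=kept.index)

        def mean_abs_corr(f: str) -> float:
            others = [g for g in kept if g != f]
            vals = [abs(r.loc[f, g]) for g in others if np.isfinite(r.loc[f, g])]
            return float(np.mean(vals)) if vals else 0.0

        # larger mean |r| dropped first; ties -> later column order
        worst = max(candidates, key=lambda f: (mean_abs_corr(f), kept.index(f)))
        kept.remove(worst)
        dropped.append(worst)
    return CorrelationReport(pairs=pairs, kept=kept, dropped=dropped)


def cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    ridge: float = 1e-4,
) -> float:
    """Stratified k-fold CV accuracy of the stress logit on (X, y).

    Folds are seeded and stratified by class; the fold count is capped by
    the smallest class count (and by n) so every fold sees every class
    where possible.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= 2:
        k = int(min(folds, counts.min(), len(y)))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        # a singleton class cannot be stratified; fall back to plain folds
        from sklearn.model_selection import KFold

        k = int(min(folds, len(y)))
        if k < 2:
            raise ValidationError("need at least 2 rows for cross-validation")
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateFitWarning)
        for train, test in skf.split(X, y):
            res = StressLogit(y[train], X[train], ridge=ridge).fit()
            correct += int(np.sum(res.classify(X[test]) == y[test]))
    return correct / len(y)


@dataclass
class SelectionResult:
    """Ordered selected features with their accuracy-gain importances."""

    ordered_features: list[str]
    importances: list[float]
    cv_accuracy_trace: list[float]
    baseline_accuracy: float
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "ordered_features": self.ordered_features,
            "importances": self.importances,
            "cv_accuracy_trace": self.cv_accuracy_trace,
            "baseline_accuracy": self.baseline_accuracy,
            "seed": self.seed,
        }


def sequential_forward_select(
    X,
    y,
    feature_names: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    min_improvement: float = 0.0,
    max_features: int | None = None,
    ridge: float = 1e-4,
) -> SelectionResult:
    """Greedy forward selection by stratified k-fold CV accuracy.

    Starts from the empty set (baseline: intercept-only model, i.e. the
    majority class of each training fold) and at every step adds the
    candidate with the highest CV accuracy, stopping once the best gain is
    no larger than ``min_improvement`` (default 0: stop at the first
    non-improving step) or ``max_features`` is reached. Fold assignment is
    seeded, so reruns with the same seed are identical.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X[feature_names].to_numpy(float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, int)
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
    if len(np.unique(y)) < 2:
        raise ValidationError("selection needs at least 2 classes present")
    if X.shape[0] < 2:
        raise ValidationError("selection needs at least 2 rows")

    baseline = cv_accuracy(np.zeros((len(y), 1)), y, folds, seed, ridge)
    selected: list[int] = []
    importances: list[float] = []
    trace: list[float] = []
    current = baseline
    remaining = list(range(X.shape[1]))
    while remaining:
        if max_features is not None and len(selected) >= max_features:
            break
        accs = [
            cv_accuracy(X[:, selected + [j]], y, folds, seed, ridge)
            for j in remaining
        ]
        best_i = int(np.argmax(accs))  # ties -> earlier feature order
        gain = accs[best_i] - current
        if gain <= min_improvement:
            break
        selected.append(remaining.pop(best_i))
        importances.append(float(gain))
        trace.append(float(accs[best_i]))
        current = accs[best_i]
    return SelectionResult(
        ordered_features=[feature_names[j] for j in selected],
        importances=importances,
        cv_accuracy_trace=trace,
        baseline_accuracy=float(baseline),
        seed=seed,
    )
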