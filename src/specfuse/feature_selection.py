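"""Frequency-based feature selection from PLS regression coefficients.

Features are ranked by the absolute regression coefficients (RCs) of a
PLS1 model fit on each training fold of a repeatedly reshuffled stratified
k-fold scheme (default 100 iterations x 6 folds, so every feature is
assessed exactly 600 times). On each fold the top ``ceil(pct/100 * n)``
features are marked selected; the selection frequency of a feature is its
count over all assessments, and the final mask keeps the ``ceil(pct/100*n)``
most frequently selected features (ties broken by larger mean |RC|, then by
lower index).

A recursive-feature-elimination helper narrows any matrix to a ranked top-k
panel with a logistic model as the base linear classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import RFE, SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_is_fitted


def percentile_count(n_features: int, pct: float) -> int:
    """Number of features kept at a percentile threshold: ``ceil(pct% of n)``."""
    if not 0 < pct <= 100:
        raise ValueError("pct must lie in (0, 100]")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return math.ceil(pct / 100.0 * n_features)


def pls_regression_coefficients(X: np.ndarray, y: np.ndarray,
                                n_latent: int = 5) -> np.ndarray:
    """Regression-coefficient vector of an ``n_latent``-component PLS1 model.

    ``y`` may be coded {0,1} or +-1; it is treated as a numeric response
    (PLS centers it internally, no additional scaling is applied because the
    block scalers have already equalized the columns).
    """
    X, y = check_X_y(X, y)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_latent <= max_comp:
        raise ValueError(
            f"n_latent={n_latent} infeasible for shape {X.shape}; "
            f"must be in [1, {max_comp}]")
    model = PLSRegression(n_components=n_latent, scale=False)
    model.fit(X, y.astype(float))
    return np.ravel(model.coef_)


@dataclass
class SelectionFrequency:
    """Per-feature selection counts across all assessments.

    ``counts`` has shape (n_features, len(percentiles)); every feature is
    assessed ``n_assessments = n_iterations * n_folds`` times per percentile.
    """

    counts: np.ndarray
    percentiles: list[float]
    n_assessments: int
    mean_abs_rc: np.ndarray

    def counts_at(self, pct: float) -> np.ndarray:
        j = self.percentiles.index(pct)
        return self.counts[:, j]


def _rank_mask(counts: np.ndarray, mean_abs_rc: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m top-count features; ties by mean |RC| then index."""
    order = np.lexsort((np.arange(counts.size), -mean_abs_rc, -counts))
    return np.sort(order[:m])


def selection_frequencies(X: np.ndarray, y: np.ndarray,
                          percentiles: list[float],
                          n_iter: int = 100, k_folds: int = 6,
                          n_latent: int = 5,
                          random_state: int | None = None) -> SelectionFrequency:
    """Accumulate selection counts for several percentile thresholds at once."""
    X, y = check_X_y(X, y)
    classes, class_counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes for stratified folds")
    if class_counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} members; "
            f"cannot build {k_folds} stratified folds")
    n_features = X.shape[1]
    cutoffs = [percentile_count(n_features, p) for p in percentiles]
    counts = np.zeros((n_features, len(percentiles)), dtype=int)
    abs_rc_sum = np.zeros(n_features)
    base = 0 if random_state is None else int(random_state)
    n_assess = 0
    for it in range(n_iter):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=(base + it) % (2 ** 31))
        for train_idx, _ in skf.split(X, y):
            rc = pls_regression_coefficients(X[train_idx], y[train_idx], n_latent)
            a = np.abs(rc)
            abs_rc_sum += a
            ranked = np.argsort(-a, kind="stable")
            for j, m in enumerate(cutoffs):
                counts[ranked[:m], j] += 1
            n_assess += 1
    return SelectionFrequency(counts, list(percentiles), n_assess,
                              abs_rc_sum / n_assess)


def frequency_selection(X: np.ndarray, y: np.ndarray, pct: float,
                        n_iter: int = 100, k_folds: int = 6,
                        n_latent: int = 5, random_state: int | None = None
                        ) -> tuple[SelectionFrequency, np.ndarray]:
    """Frequency-based feature selection at one percentile threshold.

    Returns the selection-frequency record and the final mask: the
    ``percentile_count(n, pct)`` features with the highest counts, sorted by
    index.
    """
    freq = selection_frequencies(X, y, [pct], n_iter=n_iter, k_folds=k_folds,
                                 n_latent=n_latent, random_state=random_state)
    m = percentile_count(X.shape[1], pct)
    mask = _rank_mask(freq.counts[:, 0], freq.mean_abs_rc, m)
    return freq, mask


def reevaluate_mask(X: np.ndarray, y: np.ndarray, mask: np.ndarray, pct: float,
                    n_iter: int = 100, k_folds: int = 6, n_latent: int = 5,
                    random_state: int | None = None) -> np.ndarray:
    """Second counting pass restricted to a first-pass mask.

    Re-runs the frequency procedure on the masked columns with the same
    percentile threshold to refine the importance ordering; mask membership
    and size are kept. Returns the mask ordered from most to least robustly
    selected.
    """
    mask = np.asarray(mask)
    sub = X[:, mask]
    freq = selection_frequencies(sub, y, [pct], n_iter=n_iter, k_folds=k_folds,
                                 n_latent=min(n_latent, sub.shape[1]),
                                 random_state=random_state)
    order = np.lexsort((np.arange(mask.size), -freq.mean_abs_rc,
                        -freq.counts[:, 0]))
    return mask[order]


class FrequencySelector(SelectorMixin, BaseEstimator):
    """Scikit-learn selector wrapping :func:`frequency_selection`.

    Parameters
    ----------
    pct : percentile threshold in (0, 100]; ``ceil(pct% of n)`` features kept.
    n_iter, k_folds : resampling scheme; every feature is assessed
        ``n_iter * k_folds`` times.
    n_latent : PLS1 components for the regression-coefficient ranking.
    """

    def __init__(self, pct: float = 5.0, n_iter: int = 100, k_folds: int = 6,
                 n_latent: int = 5, random_state: int | None = None):
        self.pct = pct
        self.n_iter = n_iter
        self.k_folds = k_folds
        self.n_latent = n_latent
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        self.frequencies_, self.mask_ = frequency_selection(
            X, y, self.pct, n_iter=self.n_iter, k_folds=self.k_folds,
            n_latent=self.n_latent, random_state=self.random_state)
        self.support_ = np.zeros(self.n_features_in_, dtype=bool)
        self.support_[self.mask_] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def rfe_top_k(X: np.ndarray, y: np.ndarray, k: int = 20,
              C: float = 1.0) -> np.ndarray:
    """Recursive feature elimination to a ranked top-k panel.

    A logistic model is refit repeatedly and the feature with the smallest
    absolute coefficient is dropped, one per round. The k survivors are
    returned ordered from most to least important (importance = how long a
    feature survives elimination). ``k == n_features`` performs no
    elimination and returns the input order.
    """
    X, y = check_X_y(X, y)
    n = X.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available features")
    if k == n:
        return np.arange(n)
    est = LogisticRegression(C=C, max_iter=2000)
    rfe = RFE(est, n_features_to_select=1, step=1).fit(X, y)
    order = np.argsort(rfe.ranking_, kind="stable")
    return order[:k]


__all__ = [
    "percentile_count", "pls_regression_coefficients", "SelectionFrequency",
    "selection_frequencies", "frequency_selection", "reevaluate_mask",
    "FrequencySelector", "rfe_top_k",
]
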