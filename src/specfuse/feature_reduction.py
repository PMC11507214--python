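"""PCA-based feature reduction with an incremental component scan.

Components are added one at a time (1, 2, ..., max) and the cross-validated
accuracy of a logistic model on the leading components is recorded at each
step; the scan keeps the component count with the highest accuracy, breaking
ties toward fewer components. The reduction is a best-prefix rule, not a
subset search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted


def _fix_signs(pca: PCA) -> PCA:
    # deterministic orientation: largest-magnitude loading entry positive
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[i] = -comp
    return pca


def pca_fit_transform(X_train: np.ndarray, X_test: np.ndarray,
                      n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit PCA on training rows only and project both sets.

    Component signs are fixed by making each loading's largest-magnitude
    entry positive, so scores are reproducible across SVD backends.
    """
    X_train = check_array(X_train)
    X_test = check_array(X_test)
    feasible = min(X_train.shape[0] - 1, X_train.shape[1]) if X_train.shape[0] > 1 \
        else X_train.shape[1]
    if not 1 <= n_components <= feasible:
        raise ValueError(f"n_components={n_components} infeasible; "
                         f"must be in [1, {feasible}]")
    pca = PCA(n_components=n_components, svd_solver="full").fit(X_train)
    _fix_signs(pca)
    return pca.transform(X_train), pca.transform(X_test)


@dataclass
class PcaScanResult:
    """Outcome of the incremental component scan."""

    accuracies: np.ndarray       # CV accuracy at 1..max components
    chosen: int                  # best prefix length (ties -> fewest)
    loadings: np.ndarray         # components of the chosen model
    scores: np.ndarray           # training scores of the chosen model


def pca_scan(X: np.ndarray, y: np.ndarray, max_components: int = 10,
             k_folds: int = 6, C: float = 1.0,
             random_state: int | None = None) -> PcaScanResult:
    """Scan 1..max components by cross-validated accuracy; keep the best."""
    X, y = check_X_y(X, y)
    feasible = min(X.shape[0] - X.shape[0] // k_folds - 1, X.shape[1])
    c_max = max(1, min(max_components, feasible))
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                          random_state=random_state)
    folds = list(skf.split(X, y))
    accuracies = np.zeros(c_max)
    for c in range(1, c_max + 1):
        correct = 0
        for train_idx, test_idx in folds:
            s_tr, s_te = pca_fit_transform(X[train_idx], X[test_idx], c)
            clf = LogisticRegression(C=C, max_iter=2000).fit(s_tr, y[train_idx])
            correct += int((clf.predict(s_te) == y[test_idx]).sum())
        accuracies[c - 1] = correct / X.shape[0]
    chosen = int(np.argmax(accuracies)) + 1  # argmax takes the first maximum
    pca = _fix_signs(PCA(n_components=chosen, svd_solver="full").fit(X))
    return PcaScanResult(accuracies, chosen, pca.components_.copy(),
                         pca.transform(X))


class PCAScan(BaseEstimator, TransformerMixin):
    """Transformer that picks its component count by the incremental scan.

    ``fit`` runs :func:`pca_scan` on the training data (internally
    cross-validated) and then fits a PCA with the chosen count on all
    training rows; ``transform`` projects onto those components with the
    deterministic sign convention.
    """

    def __init__(self, max_components: int = 10, k_folds: int = 6,
                 C: float = 1.0, random_state: int | None = None):
        self.max_components = max_components
        self.k_folds = k_folds
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        result = pca_scan(X, y, max_components=self.max_components,
                          k_folds=self.k_folds, C=self.C,
                          random_state=self.random_state)
        self.scan_result_ = result
        self.n_components_ = result.chosen
        self.pca_ = _fix_signs(PCA(n_components=result.chosen,
                                   svd_solver="full").fit(X))
        return self

    def transform(self, X):
        check_is_fitted(self, "pca_")
        return self.pca_.transform(check_array(X))


__all__ = ["pca_fit_transform", "pca_scan", "PcaScanResult", "PCAScan"]
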