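"""Cross-validated model fitting and metrics for the fusion configurations.

The central estimator is :class:`FusionModel`, a scikit-learn classifier
that consumes the column-wise concatenation of one or two preprocessed
spectral blocks and internally performs, per fusion option:

1. single block: unit-variance block scaling -> optional FS/FR -> logistic;
2. low-level fusion: per-block unit-variance + soft block scaling ->
   concatenation -> optional FS/FR on the fused matrix -> logistic;
3. mid-level fusion: per-block unit-variance scaling -> per-block FS/FR ->
   soft block scaling of the reduced blocks -> concatenation -> logistic;
4. high-level fusion: per-block unit-variance scaling -> optional per-block
   FS/FR -> one logistic model per block -> unweighted average of predicted
   probabilities, thresholded at 0.5 (ties positive).

All scalers, selectors and reducers are fit on training rows only, so
cross-validating the estimator is leakage-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .blocks import FTIR, SpectralBlock
from .configs import FINGERPRINT, MethodConfig
from .feature_reduction import PCAScan
from .feature_selection import FrequencySelector
from .scaling import SoftBlockScaler, UnitVarianceBlockScaler, hldf_average

FINGERPRINT_MAX_WAVENUMBER = 1800.0


def stratified_kfold(labels: np.ndarray, k: int = 6,
                     seed: int | None = None) -> np.ndarray:
    """Stratified fold assignment (fold index per sample).

    Fold sizes differ by at most one and per-fold class counts deviate from
    proportionality by at most one. ``k == n_samples`` degenerates to
    leave-one-out.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k == n:
        return np.arange(n)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members, "
                         f"cannot stratify into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def fit_binary_classifier(X_train: np.ndarray, y_train: np.ndarray,
                          C: float = 1.0) -> LogisticRegression:
    """L2-regularized logistic model; the linear workhorse of every option.

    Regularization is essential here because fused widths (up to 2883
    columns) far exceed the 30 training subjects per fold.
    """
    X_train, y_train = check_X_y(X_train, y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training data contains a single class")
    return LogisticRegression(C=C, max_iter=5000).fit(X_train, y_train)


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[np.ndarray, float]:
    """Empirical ROC points and trapezoidal AUC.

    The AUC equals the Mann-Whitney probability P(score_pos > score_neg)
    with ties counted 1/2 (U / (n1*n2)).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


class FusionModel(ClassifierMixin, BaseEstimator):
    """Multiblock fusion classifier over concatenated spectral blocks.

    Parameters
    ----------
    option : 1 single block, 2 LLDF, 3 MLDF, 4 HLDF.
    block_sizes : column widths of the constituent blocks, in order; the
        input ``X`` of ``fit``/``predict`` is their concatenation.
    reduction : ``None``, ``"fs"`` (frequency selection) or ``"fr"``
        (PCA component scan).
    fs_pct : percentile threshold(s); a single value for options 1-2, one
        value per block for options 3-4.
    threshold : decision threshold on (averaged) probabilities; ties are
        classified positive.
    """

    def __init__(self, option: int = 1, block_sizes: tuple[int, ...] = (),
                 reduction: str | None = None, fs_pct: tuple[float, ...] = (),
                 fs_n_iter: int = 100, fs_k_folds: int = 6, fs_n_latent: int = 5,
                 fr_max_components: int = 10, fr_k_folds: int = 6,
                 C: float = 1.0, threshold: float = 0.5,
                 random_state: int | None = None):
        self.option = option
        self.block_sizes = block_sizes
        self.reduction = reduction
        self.fs_pct = fs_pct
        self.fs_n_iter = fs_n_iter
        self.fs_k_folds = fs_k_folds
        self.fs_n_latent = fs_n_latent
        self.fr_max_components = fr_max_components
        self.fr_k_folds = fr_k_folds
        self.C = C
        self.threshold = threshold
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _split(self, X: np.ndarray) -> list[np.ndarray]:
        sizes = self.block_sizes or (X.shape[1],)
        if sum(sizes) != X.shape[1]:
            raise ValueError(f"block_sizes {sizes} do not partition "
                             f"{X.shape[1]} columns")
        edges = np.cumsum((0,) + tuple(sizes))
        return [X[:, a:b] for a, b in zip(edges[:-1], edges[1:])]

    def _seed(self, salt: int) -> int:
        base = 0 if self.random_state is None else int(self.random_state)
        return (base * 1009 + salt) % (2 ** 31)

    def _make_reducer(self, block_index: int):
        if self.reduction == "fs":
            pct = self.fs_pct[block_index if len(self.fs_pct) > 1 else 0]
            return FrequencySelector(pct=pct, n_iter=self.fs_n_iter,
                                     k_folds=self.fs_k_folds,
                                     n_latent=self.fs_n_latent,
                                     random_state=self._seed(7 + block_index))
        if self.reduction == "fr":
            return PCAScan(max_components=self.fr_max_components,
                           k_folds=self.fr_k_folds, C=self.C,
                           random_state=self._seed(13 + block_index))
        return None

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("FusionModel is a binary classifier")
        self.n_features_in_ = X.shape[1]
        blocks = self._split(X)
        if self.option in (1,) and len(blocks) != 1:
            raise ValueError("option 1 takes exactly one block")
        if self.option in (2, 3, 4) and len(blocks) < 1:
            raise ValueError("no blocks supplied")

        self.unit_scalers_ = [UnitVarianceBlockScaler().fit(b) for b in blocks]
        scaled = [s.transform(b) for s, b in zip(self.unit_scalers_, blocks)]
        self.reducers_ = []
        self.soft_scalers_ = []
        self.classifiers_ = []

        if self.option == 1:
            Z = self._fit_reduce(scaled[0], y, 0)
            self.classifiers_ = [fit_binary_classifier(Z, y, C=self.C)]
        elif self.option == 2:
            self.soft_scalers_ = [SoftBlockScaler().fit(b) for b in scaled]
            soft = [s.transform(b) for s, b in zip(self.soft_scalers_, scaled)]
            Z = self._fit_reduce(np.hstack(soft), y, 0)
            self.classifiers_ = [fit_binary_classifier(Z, y, C=self.C)]
        elif self.option == 3:
            reduced = [self._fit_reduce(b, y, i) for i, b in enumerate(scaled)]
            self.soft_scalers_ = [SoftBlockScaler().fit(b) for b in reduced]
            soft = [s.transform(b) for s, b in zip(self.soft_scalers_, reduced)]
            self.classifiers_ = [fit_binary_classifier(np.hstack(soft), y,
                                                       C=self.C)]
        else:  # HLDF
            for i, b in enumerate(scaled):
                Z = self._fit_reduce(b, y, i)
                self.classifiers_.append(fit_binary_classifier(Z, y, C=self.C))
        return self

    def _fit_reduce(self, Z: np.ndarray, y: np.ndarray, i: int) -> np.ndarray:
        reducer = self._make_reducer(i)
        self.reducers_.append(reducer)
        return Z if reducer is None else reducer.fit(Z, y).transform(Z)

    def _transform_blocks(self, X: np.ndarray) -> list[np.ndarray]:
        blocks = self._split(X)
        return [s.transform(b) for s, b in zip(self.unit_scalers_, blocks)]

    def predict_proba(self, X):
        check_is_fitted(self, "classifiers_")
        X = check_array(X)
        scaled = self._transform_blocks(X)
        if self.option == 1:
            Z = self._reduce(scaled[0], 0)
            probs = self.classifiers_[0].predict_proba(Z)[:, 1]
        elif self.option == 2:
            soft = [s.transform(b) for s, b in zip(self.soft_scalers_, scaled)]
            Z = self._reduce(np.hstack(soft), 0)
            probs = self.classifiers_[0].predict_proba(Z)[:, 1]
        elif self.option == 3:
            reduced = [self._reduce(b, i) for i, b in enumerate(scaled)]
            soft = [s.transform(b) for s, b in zip(self.soft_scalers_, reduced)]
            probs = self.classifiers_[0].predict_proba(np.hstack(soft))[:, 1]
        else:
            per_block = [clf.predict_proba(self._reduce(b, i))[:, 1]
                         for i, (b, clf) in enumerate(zip(scaled,
                                                          self.classifiers_))]
            probs, _ = hldf_average(per_block, threshold=self.threshold)
        return np.column_stack([1.0 - probs, probs])

    def _reduce(self, Z: np.ndarray, i: int) -> np.ndarray:
        reducer = self.reducers_[i]
        return Z if reducer is None else reducer.transform(Z)

    def predict(self, X):
        probs = self.predict_proba(X)[:, 1]
        return np.where(probs >= self.threshold, self.classes_[1],
                        self.classes_[0])

    @property
    def chosen_components_(self) -> list[int]:
        """Component counts chosen by the PCA scan, one per reduced block."""
        check_is_fitted(self, "reducers_")
        return [r.n_components_ for r in self.reducers_
                if isinstance(r, PCAScan)]


@dataclass
class EvalResult:
    """Repeated-CV evaluation of one configuration."""

    row: int
    accuracies: np.ndarray            # one pooled accuracy per repeat
    fold_accuracies: np.ndarray       # (n_repeats, k) per-fold accuracies
    aucs: np.ndarray                  # pooled-probability AUC per repeat
    roc_points: np.ndarray            # pooled ROC of the first repeat
    confusion: np.ndarray             # 2x2 counts summed over repeats
    chosen_components: list[list[int]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def se_accuracy(self) -> float:
        if self.accuracies.size < 2:
            return 0.0
        return float(self.accuracies.std(ddof=1) / np.sqrt(self.accuracies.size))

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())


def model_from_config(cfg: MethodConfig, block_sizes: tuple[int, ...],
                      fs_n_iter: int = 100, C: float = 1.0,
                      random_state: int | None = None) -> FusionModel:
    """Instantiate the estimator for one benchmark configuration."""
    return FusionModel(option=cfg.option, block_sizes=block_sizes,
                       reduction=cfg.reduction, fs_pct=tuple(cfg.fs_pct),
                       fs_n_iter=fs_n_iter,
                       fr_max_components=cfg.fr_max_components,
                       C=C, random_state=random_state)


def assemble_blocks(cfg: MethodConfig, blocks: dict[str, SpectralBlock]
                    ) -> tuple[np.ndarray, tuple[int, ...], list[SpectralBlock]]:
    """Concatenate the configuration's blocks into a design matrix.

    ``blocks`` maps modality names to preprocessed (unscaled) blocks; the
    FTIR block is restricted to the fingerprint region when required.
    """
    chosen: list[SpectralBlock] = []
    for m in cfg.modalities:
        b = blocks[m]
        if m == FTIR and cfg.ftir_range == FINGERPRINT:
            b = b.restrict(b.axis[0], FINGERPRINT_MAX_WAVENUMBER)
        chosen.append(b)
    ids = chosen[0].subject_ids
    for b in chosen[1:]:
        if b.subject_ids != ids:
            raise ValueError("subject order differs between modalities")
    X = np.hstack([b.X for b in chosen])
    return X, tuple(b.n_block for b in chosen), chosen


def run_config(cfg: MethodConfig, blocks: dict[str, SpectralBlock],
               y: np.ndarray, n_repeats: int = 100, k_folds: int = 6,
               seed: int = 0, fs_n_iter: int = 100, C: float = 1.0
               ) -> EvalResult:
    """Repeated stratified k-fold evaluation of one configuration.

    Each repeat reshuffles the stratified split; every subject is predicted
    exactly once per repeat, and the repeat accuracy pools those held-out
    predictions. The reported uncertainty is the standard error of the mean
    accuracy over repeats; AUCs come from per-repeat pooled probabilities.
    """
    y = np.asarray(y)
    X, sizes, _ = assemble_blocks(cfg, blocks)
    accuracies = np.zeros(n_repeats)
    fold_acc = np.zeros((n_repeats, k_folds))
    aucs = np.zeros(n_repeats)
    confusion = np.zeros((2, 2), dtype=int)
    roc_points = None
    chosen_components: list[list[int]] = []
    for r in range(n_repeats):
        fold_seed = (seed * 1009 + r) % (2 ** 31)
        assignment = stratified_kfold(y, k=k_folds, seed=fold_seed)
        pooled_probs = np.zeros(y.size)
        for fold in range(k_folds):
            test = assignment == fold
            train = ~test
            model = model_from_config(
                cfg, sizes, fs_n_iter=fs_n_iter, C=C,
                random_state=(seed * 7919 + r * 101 + fold) % (2 ** 31))
            model.fit(X[train], y[train])
            pooled_probs[test] = model.predict_proba(X[test])[:, 1]
            pred = model.predict(X[test])
            fold_acc[r, fold] = np.mean(pred == y[test])
            if cfg.reduction == "fr":
                chosen_components.append(model.chosen_components_)
        pred_all = (pooled_probs >= 0.5).astype(int)
        accuracies[r] = np.mean(pred_all == y)
        points, aucs[r] = roc_auc(pooled_probs, y)
        if roc_points is None:
            roc_points = points
        confusion += np.array([[np.sum((y == 0) & (pred_all == 0)),
                                np.sum((y == 0) & (pred_all == 1))],
                               [np.sum((y == 1) & (pred_all == 0)),
                                np.sum((y == 1) & (pred_all == 1))]])
    return EvalResult(cfg.row, accuracies, fold_acc, aucs, roc_points,
                      confusion, chosen_components)


__all__ = [
    "stratified_kfold", "fit_binary_classifier", "roc_auc", "FusionModel",
    "EvalResult", "run_config", "model_from_config", "assemble_blocks",
    "FINGERPRINT_MAX_WAVENUMBER",
]
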