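"""Row-wise spectral preprocessing.

The Raman pipeline is despike -> asymmetric-least-squares (AsLS) baseline
subtraction -> standard normal variate (SNV), applied per replicate, followed
by replicate averaging. The FTIR pipeline applies SNV only (absorbance
spectra acquired dry need no baseline removal) before averaging.

Conventions fixed package-wide: standard deviations use the population
divisor (``ddof=0``); AsLS penalizes second-order differences and solves the
banded normal equations with ``scipy.linalg.solveh_banded``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.linalg import solveh_banded
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .blocks import RAMAN, ReplicateSet, SpectralBlock


@dataclass
class AslsParams:
    """Asymmetric Whittaker smoother parameters.

    lam : smoothness weight on the squared second differences (default 100).
    p : asymmetry weight given to points above the baseline (default 0.01);
        points below receive ``1 - p``.
    max_iter : weight-reweighting iterations.
    tol : stop when the weight vector changes by less than this fraction.
    """

    lam: float = 100.0
    p: float = 0.01
    max_iter: int = 10
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 < self.p < 1:
            raise ValueError("p must lie strictly between 0 and 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _d2_banded(n: int) -> np.ndarray:
    """Upper banded form (3 rows) of D2'D2 for the second-difference matrix."""
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    M = (D.T @ D).todia()
    ab = np.zeros((3, n))
    for i, off in enumerate((2, 1, 0)):
        diag = M.diagonal(off)
        ab[i, off:] = diag if off else diag
    return ab


def asls_baseline(y: np.ndarray, params: AslsParams | None = None) -> np.ndarray:
    """Estimate the baseline of one spectrum by asymmetric least squares.

    Minimizes ``sum_i w_i (y_i - z_i)^2 + lam * ||D2 z||^2`` where the weights
    are re-estimated as ``p`` for points above the current baseline and
    ``1 - p`` below, until they stabilize or ``max_iter`` passes. Returns the
    baseline; the corrected spectrum is ``y - asls_baseline(y)``.
    """
    params = params or AslsParams()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("asls_baseline expects a single spectrum")
    if y.size < 4:
        raise ValueError("spectrum must have at least 4 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")

    n = y.size
    penalty = params.lam * _d2_banded(n)
    w = np.ones(n)
    z = y
    for _ in range(params.max_iter):
        ab = penalty.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        if np.abs(w_new - w).max() <= params.tol:
            w = w_new
            break
        w = w_new
    return z


def snv(y: np.ndarray) -> np.ndarray:
    """Standard normal variate: center to mean 0 and scale to unit sd.

    Uses the population sd (divisor n). Raises on zero-variance input, which
    signals a dead detector channel rather than a correctable spectrum.
    """
    y = np.asarray(y, dtype=float)
    sd = y.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot SNV-transform a zero-variance spectrum")
    return (y - y.mean(axis=-1, keepdims=True)) / sd


def despike(y: np.ndarray, window: int = 7, z_thresh: float = 8.0) -> np.ndarray:
    """Replace cosmic-ray spikes by a running median.

    A point is a spike when its residual from the mirror-padded running median
    exceeds ``z_thresh`` robust standard deviations (1.4826 * MAD of the
    residuals). All other points pass through unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    y = np.asarray(y, dtype=float)
    med = ndimage.median_filter(y, size=window, mode="mirror", axes=(-1,))
    resid = y - med
    mad = np.median(np.abs(resid), axis=-1, keepdims=True)
    sigma = 1.4826 * mad
    # dead-flat residuals: nothing can be called a spike
    with np.errstate(invalid="ignore", divide="ignore"):
        is_spike = np.where(sigma > 0, np.abs(resid) > z_thresh * sigma, False)
    return np.where(is_spike, med, y)


def average_replicates(replicates: ReplicateSet | np.ndarray) -> np.ndarray:
    """Pointwise arithmetic mean across a subject's replicate spectra."""
    X = replicates.X if isinstance(replicates, ReplicateSet) else np.asarray(replicates)
    X = np.atleast_2d(X)
    if X.shape[0] < 1:
        raise ValueError("need at least one replicate")
    return X.mean(axis=0)


class SpectralPreprocessor(BaseEstimator, TransformerMixin):
    """Row-wise preprocessing transformer for one modality.

    For ``modality='raman'`` each row is despiked, AsLS-baseline-corrected
    and SNV-normalized; for ``modality='ftir'`` only SNV is applied. The
    transformer is stateless across samples (purely row-wise), so ``fit``
    records the input width only.
    """

    def __init__(self, modality: str = RAMAN, asls_lam: float = 100.0,
                 asls_p: float = 0.01, asls_max_iter: int = 10,
                 despike_window: int = 7, despike_z: float = 8.0):
        self.modality = modality
        self.asls_lam = asls_lam
        self.asls_p = asls_p
        self.asls_max_iter = asls_max_iter
        self.despike_window = despike_window
        self.despike_z = despike_z

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        return np.vstack([self._transform_row(row) for row in X])

    def _transform_row(self, y: np.ndarray) -> np.ndarray:
        if self.modality == RAMAN:
            y = despike(y, self.despike_window, self.despike_z)
            params = AslsParams(self.asls_lam, self.asls_p, self.asls_max_iter)
            y = y - asls_baseline(y, params)
        return snv(y)


def preprocess_block(replicate_sets: dict[str, ReplicateSet] | list[ReplicateSet],
                     modality: str, **preproc_kwargs) -> SpectralBlock:
    """Preprocess every subject's replicates and average to one row each.

    Order is fixed: (despike, baseline for Raman,) SNV per replicate, then
    the pointwise mean over replicates. Returns a block with one row per
    subject, in the iteration order of ``replicate_sets``.
    """
    if isinstance(replicate_sets, dict):
        sets = list(replicate_sets.values())
    else:
        sets = list(replicate_sets)
    if not sets:
        raise ValueError("no replicate sets supplied")
    axis = sets[0].axis
    for rs in sets:
        if rs.axis.shape != axis.shape or not np.allclose(rs.axis, axis):
            raise ValueError(f"axis mismatch for subject {rs.subject_id}")
    pre = SpectralPreprocessor(modality=modality, **preproc_kwargs)
    pre.fit(sets[0].X)
    rows = [average_replicates(pre.transform(rs.X)) for rs in sets]
    return SpectralBlock(modality, axis, np.vstack(rows),
                         [rs.subject_id for rs in sets])


__all__ = [
    "AslsParams", "asls_baseline", "snv", "despike", "average_replicates",
    "SpectralPreprocessor", "preprocess_block",
]
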