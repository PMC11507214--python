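"""Column scaling within blocks and the three fusion levels.

Two block-wise column scalings are provided, both fit on training rows only:

* unit-variance block scaling — each column is centered and scaled so its
  training variance is ``1 / n_block``; the block's total training variance
  is then exactly 1, so every block contributes equally regardless of width.
* soft block scaling — each column is centered and divided by its training
  sd times the fourth root of the block width; scaled columns then share the
  training variance ``1 / sqrt(n_block)`` and the block total is
  ``sqrt(n_block)``.

Low-level fusion (LLDF) concatenates soft-scaled blocks column-wise;
high-level fusion (HLDF) averages per-block predicted probabilities, so no
block scaling is involved there at all.

All variances use the population convention (``ddof=0``), matching SNV.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .blocks import FusedBlock, SpectralBlock


class _BlockScaler(BaseEstimator, TransformerMixin):
    """Shared machinery: center columns, divide by a per-column scale."""

    def __init__(self, wavenumbers=None):
        self.wavenumbers = wavenumbers

    def _column_scale(self, sd: np.ndarray, n_block: int) -> np.ndarray:
        raise NotImplementedError

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        # a constant column's sd is ~eps after summation, not exactly zero
        dead = sd <= 1e-10 * (np.abs(self.mean_) + 1.0)
        if np.any(dead):
            idx = int(np.flatnonzero(dead)[0])
            where = (f"wavenumber {self.wavenumbers[idx]:.2f} cm^-1"
                     if self.wavenumbers is not None else f"column {idx}")
            raise ValueError(f"zero training variance at {where}")
        self.scale_ = self._column_scale(sd, X.shape[1])
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = check_array(X)
        return (X - self.mean_) / self.scale_


class UnitVarianceBlockScaler(_BlockScaler):
    """Scale so each column's training variance is ``1 / n_block``."""

    def _column_scale(self, sd, n_block):
        return sd * np.sqrt(n_block)


class SoftBlockScaler(_BlockScaler):
    """Divide each column by its sd times ``n_block ** (1/4)``."""

    def _column_scale(self, sd, n_block):
        return sd * n_block ** 0.25


def _apply_scaler(cls, block: SpectralBlock, train_rows=None) -> SpectralBlock:
    train_rows = slice(None) if train_rows is None else train_rows
    scaler = cls(wavenumbers=block.axis).fit(block.X[train_rows])
    return SpectralBlock(block.modality, block.axis, scaler.transform(block.X),
                         list(block.subject_ids))


def unit_variance_block_scale(block: SpectralBlock,
                              train_rows=None) -> SpectralBlock:
    """Unit-variance block scaling; statistics from ``train_rows`` only."""
    return _apply_scaler(UnitVarianceBlockScaler, block, train_rows)


def soft_block_scale(block: SpectralBlock, train_rows=None) -> SpectralBlock:
    """Soft block scaling; statistics from ``train_rows`` only."""
    return _apply_scaler(SoftBlockScaler, block, train_rows)


def lldf_concat(blocks: list[SpectralBlock]) -> FusedBlock:
    """Low-level fusion: column-wise concatenation preserving block order."""
    if not blocks:
        raise ValueError("need at least one block to fuse")
    ids = blocks[0].subject_ids
    for b in blocks[1:]:
        if b.subject_ids != ids:
            raise ValueError("subject order differs between blocks")
    X = np.hstack([b.X for b in blocks])
    provenance = [(b.modality, float(w)) for b in blocks for w in b.axis]
    return FusedBlock(X, provenance, list(ids))


def hldf_average(probs: list[np.ndarray], threshold: float = 0.5
                 ) -> tuple[np.ndarray, np.ndarray]:
    """High-level fusion: unweighted mean of per-block probabilities.

    Returns ``(mean_probs, labels)`` where a subject is called positive iff
    its mean probability is >= ``threshold`` (ties count as positive).
    """
    if not probs:
        raise ValueError("need at least one probability vector")
    P = np.vstack([np.asarray(p, dtype=float) for p in probs])
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    mean = P.mean(axis=0)
    return mean, (mean >= threshold).astype(int)


__all__ = [
    "UnitVarianceBlockScaler", "SoftBlockScaler", "unit_variance_block_scale",
    "soft_block_scale", "lldf_concat", "hldf_average",
]
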