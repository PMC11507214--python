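"""Core in-memory containers for spectral data.

A :class:`Spectrum` is a single intensity trace on a wavenumber axis, a
:class:`ReplicateSet` stacks the raw replicate spectra of one subject, a
:class:`SpectralBlock` is one modality's subject-by-wavenumber matrix, and a
:class:`FusedBlock` is the column-wise concatenation of several blocks with
per-column provenance so that fused feature indices can be mapped back to
(modality, wavenumber).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RAMAN = "raman"
FTIR = "ftir"


def _check_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1:
        raise ValueError("wavenumber axis must be one-dimensional")
    if axis.size >= 2 and not np.all(np.diff(axis) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    if not np.all(np.isfinite(axis)):
        raise ValueError("wavenumber axis must be finite")
    return axis


@dataclass
class Spectrum:
    """One intensity trace on a strictly increasing wavenumber axis (cm^-1)."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.shape:
            raise ValueError("axis and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class ReplicateSet:
    """Raw replicate spectra of one subject on a common axis.

    ``X`` has shape (n_replicates, n_points).
    """

    subject_id: str
    axis: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != self.axis.size:
            raise ValueError(
                f"replicates of {self.subject_id}: {self.X.shape[1]} points "
                f"do not match axis of length {self.axis.size}"
            )

    @property
    def n_replicates(self) -> int:
        return self.X.shape[0]


@dataclass
class SpectralBlock:
    """One modality's subject x wavenumber matrix."""

    modality: str
    axis: np.ndarray
    X: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != self.axis.size:
            raise ValueError("block matrix width does not match axis length")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("one subject id required per block row")

    @property
    def n_block(self) -> int:
        """Number of features (columns) in the block."""
        return self.X.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def restrict(self, lo: float, hi: float) -> "SpectralBlock":
        """Sub-block covering wavenumbers in the closed interval [lo, hi]."""
        keep = (self.axis >= lo) & (self.axis <= hi)
        return SpectralBlock(self.modality, self.axis[keep], self.X[:, keep],
                             list(self.subject_ids))


@dataclass
class FusedBlock:
    """Column-wise concatenation of blocks with per-column provenance.

    ``provenance`` holds one (modality, wavenumber) pair per fused column.
    """

    X: np.ndarray
    provenance: list[tuple[str, float]]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if len(self.provenance) != self.X.shape[1]:
            raise ValueError("provenance must list one origin per fused column")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def modality_width(self, modality: str) -> int:
        return sum(1 for m, _ in self.provenance if m == modality)
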