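"""The 25 benchmark method configurations and their feature-count arithmetic.

Each configuration is one row of the study's comparison table: a fusion
option (1 = single modality, 2 = low-level fusion, 3 = mid-level fusion,
4 = high-level fusion), the modalities involved, the FTIR spectral range
(full 400-4000 cm^-1 or fingerprint 400-1800 cm^-1) and an optional
dimensionality-reduction step — frequency-based feature selection (FS) at a
percentile, or PCA feature reduction (FR).

``nominal_feature_count`` reproduces the "Number of Features" arithmetic of
the table from the grid widths (Raman 1015, FTIR 1868 full / 727
fingerprint), the ceiling percentile rule, and — for FR rows — nominal
component counts supplied as configuration inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .blocks import FTIR, RAMAN
from .feature_selection import percentile_count

N_RAMAN = 1015
N_FTIR_FULL = 1868
N_FTIR_FP = 727

FULL = "full"
FINGERPRINT = "fingerprint"


@dataclass(frozen=True)
class MethodConfig:
    """One benchmark row: modality set, range, fusion level, FS/FR settings."""

    row: int
    option: int                       # 1 none | 2 LLDF | 3 MLDF | 4 HLDF
    label: str
    modalities: tuple[str, ...]
    ftir_range: str = FULL
    reduction: str | None = None      # None | "fs" | "fr"
    fs_pct: tuple[float, ...] = ()    # one entry (fused/single) or per block
    fr_max_components: int = 10
    nominal_pcs: tuple[int, ...] = () # table-printed PCs, arithmetic inputs

    def __post_init__(self):
        if self.option not in (1, 2, 3, 4):
            raise ValueError("option must be 1..4")
        if self.option == 4 and self.reduction == "fr" and not self.nominal_pcs:
            pass  # scan chooses at run time; nominal cells then unavailable

    def block_widths(self, n_raman: int = N_RAMAN, n_ftir_full: int = N_FTIR_FULL,
                     n_ftir_fp: int = N_FTIR_FP) -> list[int]:
        widths = []
        for m in self.modalities:
            if m == RAMAN:
                widths.append(n_raman)
            else:
                widths.append(n_ftir_full if self.ftir_range == FULL else n_ftir_fp)
        return widths


def nominal_feature_count(cfg: MethodConfig, **grid_kwargs) -> int | str:
    """The "Number of Features" cell implied by a configuration.

    Returns an int for options 1-3 and an ``"a/b"`` string for HLDF rows,
    where each block keeps its own model. FR rows use the configuration's
    nominal component counts.
    """
    widths = cfg.block_widths(**grid_kwargs)
    if cfg.option in (1, 2):
        total = sum(widths)
        if cfg.reduction is None:
            return total
        if cfg.reduction == "fs":
            return percentile_count(total, cfg.fs_pct[0])
        return cfg.nominal_pcs[0]
    if cfg.option == 3:
        if cfg.reduction == "fs":
            return sum(percentile_count(w, p) for w, p in zip(widths, cfg.fs_pct))
        return sum(cfg.nominal_pcs)
    # HLDF: independent per-block models
    if cfg.reduction is None:
        parts = widths
    elif cfg.reduction == "fs":
        parts = [percentile_count(w, p) for w, p in zip(widths, cfg.fs_pct)]
    else:
        parts = list(cfg.nominal_pcs)
    return "/".join(str(p) for p in parts)


def data_range_cell(cfg: MethodConfig) -> str:
    """The "Data Range" cell (percentiles or PC counts) for a configuration."""
    sep = " + " if cfg.option in (1, 2, 3) else "/"
    if cfg.reduction is None:
        return "100%"
    if cfg.reduction == "fs":
        return sep.join(f"{p:g}%" for p in cfg.fs_pct)
    return sep.join(f"{c}PCs" for c in cfg.nominal_pcs)


def _cfg(row, option, label, modalities, ftir_range=FULL, reduction=None,
         fs_pct=(), nominal_pcs=()):
    return MethodConfig(row=row, option=option, label=label,
                        modalities=modalities, ftir_range=ftir_range,
                        reduction=reduction, fs_pct=fs_pct,
                        nominal_pcs=nominal_pcs)


R, F = (RAMAN,), (FTIR,)
RF = (RAMAN, FTIR)

TABLE1: dict[int, MethodConfig] = {c.row: c for c in [
    _cfg(1, 1, "Raman", R),
    _cfg(2, 1, "Raman (FS)", R, reduction="fs", fs_pct=(5,)),
    _cfg(3, 1, "Raman (FR)", R, reduction="fr", nominal_pcs=(6,)),
    _cfg(4, 1, "FTIR", F),
    _cfg(5, 1, "FTIR (FS)", F, reduction="fs", fs_pct=(4,)),
    _cfg(6, 1, "FTIR (FR)", F, reduction="fr", nominal_pcs=(8,)),
    _cfg(7, 1, "FTIR", F, ftir_range=FINGERPRINT),
    _cfg(8, 1, "FTIR (FS)", F, ftir_range=FINGERPRINT, reduction="fs",
         fs_pct=(1,)),
    _cfg(9, 1, "FTIR (FR)", F, ftir_range=FINGERPRINT, reduction="fr",
         nominal_pcs=(5,)),
    _cfg(10, 2, "Raman + FTIR", RF),
    _cfg(11, 2, "Raman + FTIR + FS", RF, reduction="fs", fs_pct=(6,)),
    _cfg(12, 2, "Raman + FTIR + FR", RF, reduction="fr", nominal_pcs=(6,)),
    _cfg(13, 2, "Raman + FTIR", RF, ftir_range=FINGERPRINT),
    _cfg(14, 2, "Raman + FTIR + FS", RF, ftir_range=FINGERPRINT,
         reduction="fs", fs_pct=(10,)),
    _cfg(15, 2, "Raman + FTIR + FR", RF, ftir_range=FINGERPRINT,
         reduction="fr", nominal_pcs=(5,)),
    _cfg(16, 3, "Raman (FS) + FTIR (FS)", RF, reduction="fs", fs_pct=(5, 4)),
    _cfg(17, 3, "Raman (FR) + FTIR (FR)", RF, reduction="fr",
         nominal_pcs=(6, 8)),
    _cfg(18, 3, "Raman (FS) + FTIR (FS)", RF, ftir_range=FINGERPRINT,
         reduction="fs", fs_pct=(5, 1)),
    _cfg(19, 3, "Raman (FR) + FTIR (FR)", RF, ftir_range=FINGERPRINT,
         reduction="fr", nominal_pcs=(6, 5)),
    _cfg(20, 4, "Raman + FTIR", RF),
    _cfg(21, 4, "Raman (FS) + FTIR (FS)", RF, reduction="fs", fs_pct=(5, 4)),
    _cfg(22, 4, "Raman (FR) + FTIR (FR)", RF, reduction="fr",
         nominal_pcs=(6, 8)),
    _cfg(23, 4, "Raman + FTIR", RF, ftir_range=FINGERPRINT),
    _cfg(24, 4, "Raman (FS) + FTIR (FS)", RF, ftir_range=FINGERPRINT,
         reduction="fs", fs_pct=(5, 1)),
    _cfg(25, 4, "Raman (FR) + FTIR (FR)", RF, ftir_range=FINGERPRINT,
         reduction="fr", nominal_pcs=(6, 5)),
]}

OPTION_NAMES = {1: "No Fusion", 2: "LLDF", 3: "MLDF", 4: "HLDF"}

__all__ = ["MethodConfig", "TABLE1", "nominal_feature_count",
           "data_range_cell", "OPTION_NAMES", "FULL", "FINGERPRINT",
           "N_RAMAN", "N_FTIR_FULL", "N_FTIR_FP"]
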