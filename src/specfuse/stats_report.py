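"""Per-wavenumber statistics, band assignment, and report export.

Each wavenumber is screened with a two-sided Mann-Whitney U test between the
two cohorts (exact p-values for small tie-free samples, otherwise the
normal approximation with tie and continuity correction), annotated with the
usual significance stars, and, where possible, assigned to a vibrational
band of a known molecular class. A Benjamini-Hochberg-adjusted column is
exported alongside the raw p-values as a convenience extension; the star
labels themselves are per-wavenumber and uncorrected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import FTIR, RAMAN, FusedBlock, SpectralBlock

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 25


@dataclass
class MwuResult:
    """One Mann-Whitney U comparison."""

    wavenumber: float
    u: float
    p: float
    star: str


@dataclass
class BandAssignment:
    """A vibrational band: wavenumber range, mode, and molecular class."""

    lo: float
    hi: float
    modality: str
    mode: str
    molecular_class: str


#: Band assignments for the marker wavenumbers of the two modalities.
#: Point bands are given a +-4 cm^-1 window; ranges are as observed.
BAND_TABLE: list[BandAssignment] = [
    BandAssignment(620, 628, RAMAN,
                   "C-C twisting in lipids and proteins (phenylalanine)",
                   "protein/lipid"),
    BandAssignment(962, 970, RAMAN,
                   "CH3 deformation, ring breathing, C-C stretching in "
                   "proteins (tryptophan, valyl, prolyl) and lipids",
                   "protein/lipid"),
    BandAssignment(1048, 1054, RAMAN,
                   "=CH bending, C-C and C-O stretching in proteins "
                   "(phenylalanine), collagen and glycogen",
                   "protein/carbohydrate"),
    BandAssignment(1121, 1129, RAMAN,
                   "C-C, C-O, C-N stretching in lipids, glycogen and proteins",
                   "protein/lipid/carbohydrate"),
    BandAssignment(1244, 1252, RAMAN, "protein C-N stretching", "protein"),
    BandAssignment(1583, 1591, RAMAN, "C=C stretching in tryptophan", "protein"),
    BandAssignment(1632, 1668, RAMAN,
                   "amide I (protein secondary structure: alpha-helices, "
                   "beta-sheets)", "protein"),
    BandAssignment(1055, 1070, FTIR,
                   "PO2- symmetric stretching in phospholipids and C-O "
                   "symmetric vibrations", "lipid/nucleic acid"),
    BandAssignment(1695, 1703, FTIR,
                   "C=O stretching vibrations in amide I", "protein"),
]


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> MwuResult:
    """Two-sided Mann-Whitney U test between two groups of values.

    Uses the exact null distribution when the combined sample is small
    (n1 + n2 <= 25) and tie-free; otherwise the normal approximation with
    midrank tie handling and continuity correction. ``u`` is the U statistic
    of the first group (number of pairs where a > b, ties counting 1/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size + b.size <= _EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return MwuResult(np.nan, float(res.statistic), p, stars(p))


def stars(p: float) -> str:
    """Significance stars: **** <=1e-4, *** <=1e-3, ** <=0.01, * <=0.05."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    for label, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= cut:
            return label
    return "ns"


def assign_band(wavenumber: float, modality: str) -> BandAssignment | None:
    """Look up the band covering a wavenumber; ``None`` outside the table."""
    for band in BAND_TABLE:
        if band.modality == modality and band.lo <= wavenumber <= band.hi:
            return band
    return None


def mwu_table(block: SpectralBlock | FusedBlock, y: np.ndarray) -> pd.DataFrame:
    """Mann-Whitney screen of every column of a block.

    ``y`` is the binary response (1 = disease). Returns a tidy frame with a
    Benjamini-Hochberg column (``p_bh``) appended as an extension.
    """
    y = np.asarray(y)
    if isinstance(block, FusedBlock):
        prov = block.provenance
        X = block.X
    else:
        prov = [(block.modality, float(w)) for w in block.axis]
        X = block.X
    rows = []
    for j, (modality, w) in enumerate(prov):
        r = mann_whitney_u(X[y == 1, j], X[y == 0, j])
        rows.append((modality, w, r.u, r.p, r.star))
    df = pd.DataFrame(rows, columns=["modality", "wavenumber", "U", "p", "star"])
    df["p_bh"] = stats.false_discovery_control(df["p"].to_numpy())
    return df


def top_feature_table(fused: FusedBlock, y: np.ndarray,
                      ranked_columns: np.ndarray) -> pd.DataFrame:
    """Annotated table for a ranked feature panel (descending importance)."""
    y = np.asarray(y)
    rows = []
    for rank, j in enumerate(np.asarray(ranked_columns), start=1):
        modality, w = fused.provenance[int(j)]
        r = mann_whitney_u(fused.X[y == 1, int(j)], fused.X[y == 0, int(j)])
        band = assign_band(w, modality)
        rows.append((rank, modality, w, r.u, r.p, r.star,
                     band.mode if band else "",
                     band.molecular_class if band else ""))
    return pd.DataFrame(rows, columns=[
        "rank", "modality", "wavenumber", "U", "p", "star",
        "assignment", "molecular_class"])


def export_report(directory: str | Path, *,
                  mwu: pd.DataFrame | None = None,
                  top_features: pd.DataFrame | None = None,
                  boxplot_data: pd.DataFrame | None = None,
                  scores: dict[str, pd.DataFrame] | None = None,
                  coefficients: dict[str, pd.DataFrame] | None = None,
                  manifest: dict | None = None) -> list[Path]:
    """Write the report files backing the score/coefficient/box plots.

    Any section passed as ``None`` is skipped; the absence of a top-feature
    panel (no FS run) is logged rather than treated as an error.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str):
        path = directory / name
        df.to_csv(path, index=False)
        written.append(path)

    if mwu is not None:
        _write(mwu, "mwu_per_wavenumber.csv")
    if top_features is not None:
        _write(top_features, "top_features.csv")
    else:
        logger.info("no feature-selection panel available; "
                    "top-feature table omitted")
    if boxplot_data is not None:
        _write(boxplot_data, "top_feature_boxplot_data.csv")
    for label, df in (scores or {}).items():
        _write(df, f"scores_{label}.csv")
    for label, df in (coefficients or {}).items():
        _write(df, f"regression_coefficients_{label}.csv")
    if manifest is not None:
        path = directory / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(path)
    return written


__all__ = [
    "MwuResult", "BandAssignment", "BAND_TABLE", "mann_whitney_u", "stars",
    "assign_band", "mwu_table", "top_feature_table", "export_report",
]
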