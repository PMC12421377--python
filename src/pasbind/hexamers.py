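"""PAS hexamer taxonomy, oligo construction, fold-change ratios and the
frequency-vs-affinity correlation.

The canonical polyadenylation signal is AAUAAA; nearly all other signals seen
in human mRNAs are single-nucleotide variants of it (or, rarely, of AUUAAA).
The six positions fall into three pairs recognized by distinct protein
surfaces of mPSF — A1-A2 and A4-A5 by zinc fingers of CPSF30, and U3-A6
(a Hoogsteen base pair) by WDR33 — which motivates the position-group
classification used here.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL",
    "SECONDARY",
    "HexamerRecord",
    "CorrelationResult",
    "hamming",
    "classify_variant",
    "build_oligo",
    "ratio_table",
    "display_ratio",
    "loglog_correlation",
    "load_reference_table",
    "reference_records",
    "group_kd_ranges",
]

CANONICAL = "AAUAAA"
SECONDARY = "AUUAAA"

RNA_ALPHABET = frozenset("ACGU")

# position-pair groups: 1-based hexamer positions -> group label
_POSITION_GROUP = {1: "A1A2", 2: "A1A2", 3: "U3A6", 6: "U3A6", 4: "A4A5", 5: "A4A5"}

FLANK_5 = "UGC"
FLANK_3 = "CAA"


def _check_hexamer(h: str) -> str:
    if not isinstance(h, str) or len(h) != 6:
        raise ValueError(f"expected a 6-nt hexamer, got {h!r}")
    if not set(h) <= RNA_ALPHABET:
        raise ValueError(f"hexamer must use the RNA alphabet ACGU, got {h!r}")
    return h


def hamming(h1: str, h2: str) -> int:
    """Number of mismatching positions between two equal-length RNA strings."""
    if len(h1) != len(h2):
        raise ValueError(f"length mismatch: {h1!r} vs {h2!r}")
    for h in (h1, h2):
        if not set(h) <= RNA_ALPHABET:
            raise ValueError(f"RNA alphabet ACGU required, got {h!r}")
    return sum(a != b for a, b in zip(h1, h2))


def classify_variant(hexamer: str) -> str:
    """Position-group class of a hexamer relative to AAUAAA.

    * ``canonical`` — AAUAAA itself;
    * ``A1A2`` / ``U3A6`` / ``A4A5`` — single-nucleotide variants of AAUAAA,
      grouped by which recognition pair the varied position belongs to;
    * ``AUUAAA_derived`` — >=2 changes from AAUAAA but a single change from
      AUUAAA;
    * ``other`` — everything else.
    """
    _check_hexamer(hexamer)
    if hexamer == CANONICAL:
        return "canonical"
    d1 = hamming(hexamer, CANONICAL)
    if d1 == 1:
        pos = next(i for i, (a, b) in enumerate(zip(hexamer, CANONICAL), 1) if a != b)
        return _POSITION_GROUP[pos]
    if hamming(hexamer, SECONDARY) == 1:
        return "AUUAAA_derived"
    return "other"


def build_oligo(hexamer: str) -> str:
    """12-mer assay oligo: UGC + hexamer + CAA (SV40-late-derived flanks)."""
    return FLANK_5 + _check_hexamer(hexamer) + FLANK_3


def display_ratio(raw: float) -> float:
    """Presentation rounding of a Kd fold-change: half-to-even, to the nearest
    integer for ratios >= 1 and to one decimal below 1."""
    if raw >= 1:
        return float(round(raw))
    return round(raw, 1)


def ratio_table(
    kd_map: dict[str, float], reference: str = CANONICAL
) -> dict[str, dict[str, float]]:
    """Fold change of each Kd relative to the reference hexamer.

    Returns ``{hexamer: {"raw": kd/kd_ref, "display": rounded}}``; the raw
    ratio is always retained alongside the presentation-rounded one.
    """
    if reference not in kd_map:
        raise ValueError(f"reference hexamer {reference!r} missing from kd_map")
    kd_ref = kd_map[reference]
    if not kd_ref > 0:
        raise ValueError("reference Kd must be > 0")
    out: dict[str, dict[str, float]] = {}
    for h, kd in kd_map.items():
        raw = kd / kd_ref
        out[h] = {"raw": raw, "display": display_ratio(raw)}
    return out


@dataclass
class HexamerRecord:
    """One hexamer with its taxonomy, annotation frequency and affinity."""

    hexamer: str
    frequency: float | None = None  # percent of annotated signals
    kd: float | None = None  # nM
    ratio: float | None = None  # raw fold change vs AAUAAA
    dist_canonical: int = field(init=False)
    dist_secondary: int = field(init=False)
    group: str = field(init=False)

    def __post_init__(self) -> None:
        _check_hexamer(self.hexamer)
        self.dist_canonical = hamming(self.hexamer, CANONICAL)
        self.dist_secondary = hamming(self.hexamer, SECONDARY)
        self.group = classify_variant(self.hexamer)


@dataclass(frozen=True)
class CorrelationResult:
    """Log-log frequency-vs-Kd regression summary."""

    pearson_r_loglog: float
    slope_loglog: float
    intercept_loglog: float
    spearman_rho: float
    outliers: tuple[str, ...]
    n: int


def loglog_correlation(
    records: list[HexamerRecord], outlier_threshold: float = 2.0
) -> CorrelationResult:
    """OLS of log10(frequency) on log10(Kd), plus Spearman rho on raw pairs.

    Outliers are records whose standardized log-log residual exceeds
    ``outlier_threshold`` in absolute value (a descriptive flag, not a test).
    Requires >= 3 records with positive frequency and Kd.
    """
    usable = [r for r in records if r.frequency and r.kd and r.frequency > 0 and r.kd > 0]
    # canonical ordering makes the result invariant to input permutation
    usable.sort(key=lambda r: (r.kd, r.frequency, r.hexamer))
    if len(usable) < 3:
        raise ValueError(f"need >= 3 records with frequency > 0 and kd > 0, got {len(usable)}")
    freq = np.array([r.frequency for r in usable], dtype=float)
    kd = np.array([r.kd for r in usable], dtype=float)
    x, y = np.log10(kd), np.log10(freq)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sd = resid.std(ddof=2) if len(usable) > 2 else 0.0
    if sd > 0:
        flagged = tuple(
            r.hexamer for r, z in zip(usable, resid / sd) if abs(z) > outlier_threshold
        )
    else:
        flagged = ()
    rho = stats.spearmanr(kd, freq).statistic
    return CorrelationResult(
        pearson_r_loglog=float(fit.rvalue),
        slope_loglog=float(fit.slope),
        intercept_loglog=float(fit.intercept),
        spearman_rho=float(rho),
        outliers=flagged,
        n=len(usable),
    )


def load_reference_table() -> pd.DataFrame:
    """Packaged reference panel: 12-mer sequence, hexamer, label, annotation
    frequency (%), measured Kd (nM, NaN where not determined) and the
    published display ratio."""
    ref = importlib.resources.files("pasbind.data") / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["nd"])
    return df


def reference_records(include_labeled: bool = False) -> list[HexamerRecord]:
    """Reference panel as HexamerRecords (one per unlabeled oligo by default).

    The FAM-labeled probe row duplicates the AAUAAA hexamer and reflects the
    label's effect on binding, so correlation analyses exclude it unless
    ``include_labeled`` is set.
    """
    df = load_reference_table()
    if not include_labeled:
        df = df[df["label"] != "FAM"]
    out = []
    for _, row in df.iterrows():
        kd = None if pd.isna(row["kd_nM"]) else float(row["kd_nM"])
        out.append(
            HexamerRecord(
                hexamer=row["hexamer"],
                frequency=float(row["frequency_percent"]),
                kd=kd,
                ratio=None,
            )
        )
    return out


def group_kd_ranges(records: list[HexamerRecord]) -> dict[str, tuple[float, float]]:
    """Per position-group (min, max) Kd among records with a measured Kd.

    Only the single-nucleotide variant groups (A1A2, U3A6, A4A5) are reported;
    the canonical hexamer anchors the ratios and is not a variant group.
    """
    out: dict[str, tuple[float, float]] = {}
    for grp in ("A1A2", "U3A6", "A4A5"):
        kds = [r.kd for r in records if r.group == grp and r.kd]
        if kds:
            out[grp] = (min(kds), max(kds))
    return out
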