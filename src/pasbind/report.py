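"""Assembly of the combined hexamer report: taxonomy + frequency + Kd +
fold-change ratio + log-log correlation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hexamers import (
    CANONICAL,
    CorrelationResult,
    HexamerRecord,
    display_ratio,
    loglog_correlation,
)

__all__ = ["assemble_report"]


def assemble_report(
    freq_map: dict[str, float],
    kd_map: dict[str, float] | None = None,
    reference: str = CANONICAL,
    outlier_threshold: float = 2.0,
) -> tuple[pd.DataFrame, CorrelationResult | None]:
    """Join frequencies (%) with Kds (nM) into one table per hexamer.

    Hexamers without a Kd stay in the table (frequency-only rows) but are
    excluded from the ratio column and the correlation.  The correlation is
    computed when >= 3 hexamers carry both quantities, else returned as None.
    """
    kd_map = kd_map or {}
    if kd_map and reference not in kd_map:
        raise ValueError(f"reference hexamer {reference!r} has no Kd")
    kd_ref = kd_map.get(reference)
    records = []
    rows = []
    for h in sorted(freq_map, key=lambda h: -freq_map[h]):
        kd = kd_map.get(h)
        raw = kd / kd_ref if kd is not None and kd_ref else np.nan
        rec = HexamerRecord(hexamer=h, frequency=freq_map[h], kd=kd,
                            ratio=None if np.isnan(raw) else raw)
        records.append(rec)
        rows.append({
            "hexamer": h,
            "group": rec.group,
            "dist_AAUAAA": rec.dist_canonical,
            "dist_AUUAAA": rec.dist_secondary,
            "frequency_percent": freq_map[h],
            "kd_nM": kd if kd is not None else np.nan,
            "ratio_raw": raw,
            "ratio_display": display_ratio(raw) if not np.isnan(raw) else np.nan,
        })
    frame = pd.DataFrame(rows)
    with_both = [r for r in records if r.kd and r.frequency]
    corr = loglog_correlation(with_both, outlier_threshold) if len(with_both) >= 3 else None
    return frame, corr
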