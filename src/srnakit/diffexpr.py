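"""Ratio-based differential expression between tissue pairs.

With one library per tissue there are no replicates, so no count model and
no p-values: miRNAs are ranked by the plain RPM ratio and filtered by a
minimum fold change (> 1.5) and a minimum expression level (> 1000 RPM in
the higher tissue).  Every record carries a ``putative`` flag to make the
single-transcriptome caveat explicit in the output schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

COLUMNS = ["mirna_id", "tissue_high", "tissue_low", "rpm_high", "rpm_low",
           "fold", "fold_rounded", "putative"]


@dataclass(slots=True)
class FoldChangeRecord:
    mirna_id: str
    tissue_high: str
    tissue_low: str
    rpm_high: float
    rpm_low: float
    fold: float
    fold_rounded: int | None
    passes: bool


def fold_change(rpm_a: float, rpm_b: float) -> tuple[float, int | None]:
    """RPM ratio a/b and its nearest integer (half away from zero).

    A zero denominator yields (inf, None); such records are flagged and
    listed separately, never ranked.
    """
    if rpm_a < 0 or rpm_b < 0:
        raise ValueError("RPM values must be non-negative")
    if rpm_b == 0:
        return (math.inf, None)
    fold = rpm_a / rpm_b
    return (fold, int(math.floor(fold + 0.5)))


def differential_table(
    rpm: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    min_fold: float = 1.5,
    min_rpm: float = 1000.0,
    top_n: int = 5,
) -> dict[str, pd.DataFrame]:
    """Top differentially expressed miRNAs in both directions.

    ``rpm`` is a family x tissue RPM matrix.  Each direction keeps records
    with fold > ``min_fold`` and RPM of the *higher* tissue > ``min_rpm``,
    ranked by descending fold (ties: higher rpm_high, then id), truncated
    to ``top_n``.  Families absent from the lower tissue (RPM 0) are
    returned under ``"infinite"`` instead of being ranked.
    """
    for tissue in (tissue_a, tissue_b):
        if tissue not in rpm.columns:
            raise KeyError(f"tissue {tissue!r} not in expression matrix")

    def one_direction(high: str, low: str) -> tuple[pd.DataFrame, list[dict]]:
        rows, infinite = [], []
        for mirna_id, row in rpm.iterrows():
            rpm_high, rpm_low = float(row[high]), float(row[low])
            if rpm_high <= min_rpm:
                continue
            fold, rounded = fold_change(rpm_high, rpm_low)
            record = {
                "mirna_id": mirna_id, "tissue_high": high, "tissue_low": low,
                "rpm_high": rpm_high, "rpm_low": rpm_low,
                "fold": fold, "fold_rounded": rounded, "putative": True,
            }
            if math.isinf(fold):
                infinite.append(record)
            elif fold > min_fold:
                rows.append(record)
        rows.sort(key=lambda r: (-r["fold"], -r["rpm_high"], str(r["mirna_id"])))
        return pd.DataFrame(rows[:top_n], columns=COLUMNS), infinite

    a_table, a_inf = one_direction(tissue_a, tissue_b)
    b_table, b_inf = one_direction(tissue_b, tissue_a)
    infinite = pd.DataFrame(a_inf + b_inf, columns=COLUMNS)
    return {"a_greater": a_table, "b_greater": b_table, "infinite": infinite}
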