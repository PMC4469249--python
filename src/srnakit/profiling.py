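"""Expression profiling: RPM normalization, matrices, size distributions.

Two different RPM denominators are used, on purpose:

* miRNA expression is normalized per million **18-25 nt** reads of the
  tissue (the annotatable size window);
* size distributions are normalized per million **1-35 nt** reads.

Both denominators are logged per tissue so they cannot be silently mixed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .annotate import MIRNA_TIERS, PUTATIVE, TIERS, AnnotationResult
from .io_formats import SmallRNARead

logger = logging.getLogger("srnakit.profiling")

MAX_LEN = 35


def compute_rpm(raw_count: int, total_18_25: int) -> float:
    """Reads per million: raw_count / total_18_25 * 1e6.  No pseudocounts."""
    if total_18_25 < 1:
        raise ValueError("total_18_25 must be >= 1")
    if raw_count > total_18_25:
        raise ValueError("raw_count cannot exceed the library total")
    return raw_count / total_18_25 * 1e6


def total_18_25(results: Sequence[AnnotationResult]) -> int:
    """Denominator for expression RPM: all annotated-window reads, any tier."""
    return sum(r.count for r in results)


def expression_matrix(
    results_by_tissue: Mapping[str, Sequence[AnnotationResult]],
) -> dict[str, pd.DataFrame | pd.Series]:
    """Family x tissue expression tables from per-tissue annotation results.

    Only tiers 1-3 contribute to a family's raw count; putative-miRNA reads
    are tabulated in a separate pair of tables.  Missing family/tissue
    combinations are 0.  Returns a dict with ``raw``, ``rpm``,
    ``putative_raw``, ``putative_rpm`` DataFrames and the per-tissue
    ``totals`` Series (the 18-25 nt denominators).
    """
    tissues = list(results_by_tissue)
    totals = pd.Series(
        {t: total_18_25(results_by_tissue[t]) for t in tissues}, name="total_18_25"
    )
    for tissue, total in totals.items():
        logger.info("expression denominator (18-25 nt reads) for %s: %d", tissue, total)

    def counts(tiers: tuple[str, ...]) -> pd.DataFrame:
        rows: dict[str, dict[str, int]] = {}
        for tissue in tissues:
            for res in results_by_tissue[tissue]:
                if res.tier in tiers and res.family:
                    rows.setdefault(res.family, {t: 0 for t in tissues})
                    rows[res.family][tissue] += res.count
        df = pd.DataFrame.from_dict(rows, orient="index", dtype="int64")
        if df.empty:
            return pd.DataFrame(columns=tissues, dtype="int64")
        return df.reindex(columns=tissues, fill_value=0).sort_index()

    raw = counts(MIRNA_TIERS)
    putative_raw = counts((PUTATIVE,))

    def to_rpm(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return df.astype(float)
        return df.div(totals.where(totals > 0, other=pd.NA), axis=1) * 1e6

    return {
        "raw": raw,
        "rpm": to_rpm(raw),
        "putative_raw": putative_raw,
        "putative_rpm": to_rpm(putative_raw),
        "totals": totals,
    }


def size_distribution(reads: Sequence[SmallRNARead], tissue: str = "") -> pd.Series:
    """Per-length read totals scaled to one million 1-35 nt reads."""
    if not reads:
        raise ValueError("size_distribution of an empty library is undefined")
    counts = pd.Series(0, index=range(1, MAX_LEN + 1), dtype="int64")
    for read in reads:
        n = len(read.sequence)
        if 1 <= n <= MAX_LEN:
            counts[n] += read.count
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no reads in the 1-35 nt window")
    logger.info("size-distribution denominator (1-35 nt reads) for %s: %d", tissue, total)
    scaled = counts / total * 1e6
    scaled.name = tissue or "reads_per_million"
    scaled.index.name = "length"
    return scaled


def category_proportions(
    results: Sequence[AnnotationResult], stratify_by_length: bool = False
) -> pd.Series | pd.DataFrame:
    """Fractions of the 18-25 nt population per annotation tier.

    Unstratified: a Series over the five tiers summing to 1.  Stratified: a
    DataFrame indexed by read length 18-25 whose rows each sum to 1 (rows
    with no reads are 0).
    """
    if not stratify_by_length:
        totals = pd.Series({t: 0 for t in TIERS}, dtype="float")
        for res in results:
            totals[res.tier] += res.count
        grand = totals.sum()
        return totals / grand if grand > 0 else totals

    table = pd.DataFrame(0.0, index=range(18, 26), columns=list(TIERS))
    for res in results:
        table.loc[len(res.sequence), res.tier] += res.count
    sums = table.sum(axis=1)
    return table.div(sums.where(sums > 0, other=1.0), axis=0)
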