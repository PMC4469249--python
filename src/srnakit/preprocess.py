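"""Quality filtering, 3' adapter trimming, read collapsing, length selection.

Adapter trimming deliberately retains adapter fragments shorter than the
minimum overlap (default 4 nt): a 1-3 nt 3' suffix cannot be distinguished
from genuine small RNA sequence, so reads carrying only such a fragment are
left at full length.  On fixed 35-nt raw reads this leaves the trimmed
length distribution with a characteristic hole: lengths 32-34 cannot occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import SmallRNARead

logger = logging.getLogger("srnakit.preprocess")


@dataclass(slots=True)
class TrimResult:
    sequence: str
    trimmed_length: int
    adapter_found: bool


def _find_adapter_start(seq: str, adapter: str, min_overlap: int) -> int | None:
    """Leftmost position where the adapter starts.

    A hit is either a full adapter occurrence (anything 3' of it is
    discarded too) or a 3'-terminal fragment that is a prefix of the
    adapter of length >= ``min_overlap``.
    """
    la = len(adapter)
    for p in range(0, len(seq) - min_overlap + 1):
        k = min(la, len(seq) - p)
        if seq[p : p + k] == adapter[:k]:
            return p
    return None


def trim_adapter(sequence: str, adapter: str, min_overlap: int = 4) -> TrimResult:
    """Trim the 3' adapter from a read; fragments of < ``min_overlap`` nt stay.

    Trimming is repeated until no eligible adapter match remains, so the
    operation is idempotent even when an insert itself ends in a short
    adapter prefix.
    """
    if len(adapter) < min_overlap:
        raise ValueError(
            f"adapter length {len(adapter)} is shorter than min_overlap {min_overlap}"
        )
    seq = sequence
    found = False
    while True:
        p = _find_adapter_start(seq, adapter, min_overlap)
        if p is None:
            break
        seq = seq[:p]
        found = True
    return TrimResult(sequence=seq, trimmed_length=len(seq), adapter_found=found)


def quality_filter(
    reads: list[SmallRNARead], min_mean_q: int = 20
) -> list[SmallRNARead]:
    """Drop reads whose mean Phred quality is below ``min_mean_q``.

    Reads without quality information (FASTA input) are kept unchanged and
    a warning is logged once.
    """
    kept: list[SmallRNARead] = []
    removed = 0
    warned = False
    for read in reads:
        if read.mean_quality is None:
            if not warned:
                logger.warning("quality_filter: reads carry no quality values; passing through")
                warned = True
            kept.append(read)
        elif read.mean_quality >= min_mean_q:
            kept.append(read)
        else:
            removed += 1
    logger.info("quality_filter removed %d of %d reads", removed, len(reads))
    return kept


def collapse(reads: list[SmallRNARead]) -> list[SmallRNARead]:
    """Merge identical sequences into one record with summed counts.

    All reads must share a tissue label.  Output is sorted by descending
    count then sequence, which makes downstream tables deterministic.
    """
    tissues = {r.tissue for r in reads}
    if len(tissues) > 1:
        raise ValueError(f"collapse requires a single tissue, got {sorted(tissues)}")
    tissue = tissues.pop() if tissues else ""
    counts: dict[str, int] = {}
    for read in reads:
        counts[read.sequence] = counts.get(read.sequence, 0) + read.count
    collapsed = [
        SmallRNARead(sequence=seq, count=n, tissue=tissue)
        for seq, n in counts.items()
    ]
    collapsed.sort(key=lambda r: (-r.count, r.sequence))
    return collapsed


def select_length(
    reads: list[SmallRNARead], lo: int, hi: int
) -> list[SmallRNARead]:
    """Keep reads with lo <= length <= hi (counts untouched)."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must be <= hi ({hi})")
    return [r for r in reads if lo <= len(r.sequence) <= hi]
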