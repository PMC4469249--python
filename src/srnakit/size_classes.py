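"""Non-miRNA population structure: repeat-derived reads and putative piRNAs.

Reads of 26-31 nt that match a repetitive-element reference are flagged as
putative piRNAs — the length class and repeat origin characteristic of
PIWI-interacting RNAs, which dominate gonadal small RNA libraries.  Repeat
assignment is an exact-substring criterion against a user-supplied repeat
FASTA (configurable minimum exact match, default 20 nt, checked on both
strands); it is an explicit stand-in for a full homology search, not a
reconstruction of one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotate import MIRNA_TIERS, PUTATIVE, AnnotationResult
from .io_formats import SmallRNARead

logger = logging.getLogger("srnakit.size_classes")

CATEGORIES = ("miRNA", "putative_miRNA", "repeat_derived", "other_annotated", "unidentified")
PIRNA_MIN_LEN = 26
PIRNA_MAX_LEN = 31

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RepeatIndex:
    """k-mer set over a repeat reference (both strands) for substring tests."""

    def __init__(self, repeats: Sequence[tuple[str, str]], min_exact: int = 20):
        if min_exact < 1:
            raise ValueError("min_exact must be positive")
        self.min_exact = min_exact
        self.kmers: set[str] = set()
        for _rid, seq in repeats:
            for strand_seq in (seq, reverse_complement(seq)):
                for i in range(len(strand_seq) - min_exact + 1):
                    self.kmers.add(strand_seq[i : i + min_exact])
        if not repeats:
            logger.warning("RepeatIndex built from an empty repeat set; nothing will match")

    def matches(self, read: str) -> bool:
        k = self.min_exact
        if len(read) < k:
            return False
        return any(read[i : i + k] in self.kmers for i in range(len(read) - k + 1))


def repeat_match(
    read: str, repeats: RepeatIndex | Sequence[tuple[str, str]], min_exact: int = 20
) -> bool:
    """True iff the read (either strand) shares an exact >= min_exact nt
    substring with any repeat sequence."""
    index = repeats if isinstance(repeats, RepeatIndex) else RepeatIndex(repeats, min_exact)
    return index.matches(read)


def flag_putative_pirna(read: str, repeats: RepeatIndex) -> bool:
    """26-31 nt and repeat-derived."""
    return PIRNA_MIN_LEN <= len(read) <= PIRNA_MAX_LEN and repeats.matches(read)


@dataclass(slots=True)
class CompositionSummary:
    """Category fractions of a tissue's 1-35 nt small RNA population."""

    tissue: str
    fractions: pd.Series
    putative_pirna_fraction: float
    # first-nucleotide composition of the putative-piRNA reads (1U bias is a
    # classic piRNA diagnostic); reported, no threshold applied
    pirna_first_nt: pd.Series = field(default_factory=pd.Series)


def composition_summary(
    reads: Sequence[SmallRNARead],
    results: Sequence[AnnotationResult],
    repeats: RepeatIndex,
    tissue: str = "",
) -> CompositionSummary:
    """Assign every 1-35 nt read one category and summarize fractions.

    Precedence: miRNA (tiers 1-3) > putative_miRNA > repeat_derived >
    unidentified.  The ``other_annotated`` category is part of the schema
    but stays 0 here: no non-miRNA annotation source is wired in.
    """
    tier_by_seq: dict[str, str] = {r.sequence: r.tier for r in results}
    counts = {c: 0 for c in CATEGORIES}
    pirna_count = 0
    first_nt = {nt: 0 for nt in "ACGT"}
    total = 0
    for read in reads:
        n = len(read.sequence)
        if not 1 <= n <= 35:
            continue
        total += read.count
        tier = tier_by_seq.get(read.sequence)
        if tier in MIRNA_TIERS:
            counts["miRNA"] += read.count
            continue
        if tier == PUTATIVE:
            counts["putative_miRNA"] += read.count
            continue
        if repeats.matches(read.sequence):
            counts["repeat_derived"] += read.count
            if PIRNA_MIN_LEN <= n <= PIRNA_MAX_LEN:
                pirna_count += read.count
                first_nt[read.sequence[0]] += read.count
        else:
            counts["unidentified"] += read.count
    if total == 0:
        raise ValueError("composition_summary of an empty library is undefined")
    fractions = pd.Series({c: counts[c] / total for c in CATEGORIES})
    pirna_total = max(pirna_count, 1)
    return CompositionSummary(
        tissue=tissue,
        fractions=fractions,
        putative_pirna_fraction=pirna_count / total,
        pirna_first_nt=pd.Series({nt: first_nt[nt] / pirna_total for nt in "ACGT"}),
    )
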