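"""Four-tier homology classifier for 18-25 nt small RNA reads.

Each read is assigned exactly one class by a cascade against a mature-miRNA
reference set:

tier 1
    an ungapped placement against some reference with at most 2 nt of 5'
    offset and 4 nt of 3' offset in which every overlapping position is
    identical (nucleotides extending past the reference ends are
    unconstrained — no precursor context is available to check them);
tier 2
    among references sharing the read's first 10 nt, a 5'-anchored
    position-wise comparison contains a contiguous identical run of
    >= 16 nt;
tier 3
    same candidate set, longest run < 16 but the Smith-Waterman local
    alignment score (match +5, mismatch −4, affine gaps) is >= 70;
putative miRNA
    the 10-nt prefix is shared but none of the above holds;
unannotated
    no reference shares the 10-nt prefix and tier 1 fails everywhere.

A read matched to any species' mature entry is reported under the
``fru-``-prefixed family name of that entry, the convention for conserved
miRNAs observed in a new species.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .io_formats import MatureReference, SmallRNARead, strip_species_prefix

logger = logging.getLogger("srnakit.annotate")

TIER1 = "miRNA_tier1"
TIER2 = "miRNA_tier2"
TIER3 = "miRNA_tier3"
PUTATIVE = "putative_miRNA"
UNANNOTATED = "unannotated"
TIERS = (TIER1, TIER2, TIER3, PUTATIVE, UNANNOTATED)
MIRNA_TIERS = (TIER1, TIER2, TIER3)


@dataclass(slots=True)
class AlignmentParams:
    """Scoring and tolerance constants of the annotation cascade.

    Match/mismatch (+5/−4), the Smith-Waterman threshold (70), the
    contiguous-run threshold (16 nt), the prefix length (10 nt) and the
    5'/3' offset tolerances (2/4 nt) are the method's constants.  The gap
    penalties are configurable: a gap of length k scores
    ``gap_open + (k−1)·gap_extend``.
    """

    match_score: int = 5
    mismatch_score: int = -4
    gap_open: int = -12
    gap_extend: int = -4
    sw_threshold: int = 70
    min_contiguous: int = 16
    prefix_len: int = 10
    max_5p_offset: int = 2
    max_3p_offset: int = 4
    use_gaps: bool = True

    def __post_init__(self) -> None:
        if not (self.match_score > 0 > self.mismatch_score):
            raise ValueError("require match_score > 0 > mismatch_score")
        if self.sw_threshold <= 0:
            raise ValueError("sw_threshold must be positive")


@dataclass(slots=True)
class AnnotationResult:
    """Tier call for one collapsed read.

    ``offset_5p`` is read start minus reference start (negative = the read
    extends 5' of the reference); ``offset_3p`` is read end minus reference
    end.  For tier 2/3/putative calls the 5' offset is 0 by construction
    (prefix identity) and the 3' offset is the length difference.
    """

    sequence: str
    count: int
    tissue: str
    tier: str
    matched_id: str | None = None
    family: str | None = None
    offset_5p: int | None = None
    offset_3p: int | None = None
    longest_run: int | None = None
    sw_score: int | None = None


def fru_family(ref_id: str) -> str:
    """Output family name with the ``fru-`` species prefix."""
    return "fru-" + strip_species_prefix(ref_id)


def sw_score(a: str, b: str, params: AlignmentParams | None = None) -> int:
    """Smith-Waterman local alignment score (Gotoh affine-gap recurrence).

    The empty alignment scores 0, so the result is never negative; the
    score is symmetric in its arguments.  With ``use_gaps=False`` only
    ungapped local alignments are considered.
    """
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("sw_score requires non-empty sequences")
    match, mismatch = params.match_score, params.mismatch_score
    gap_open, gap_ext = params.gap_open, params.gap_extend
    n, m = len(a), len(b)
    NEG = -(10**9)
    best = 0
    prev_h = [0] * (m + 1)
    f_col = [NEG] * (m + 1)  # gap in b (vertical), carried down each column
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur_h = [0] * (m + 1)
        e = NEG  # gap in a (horizontal), carried along the row
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            if params.use_gaps:
                e = max(cur_h[j - 1] + gap_open, e + gap_ext)
                f_col[j] = max(prev_h[j] + gap_open, f_col[j] + gap_ext)
                h = max(0, prev_h[j - 1] + s, e, f_col[j])
            else:
                h = max(0, prev_h[j - 1] + s)
            cur_h[j] = h
            if h > best:
                best = h
        prev_h = cur_h
    return best


def tier1_match(
    read: str, ref: MatureReference | str, params: AlignmentParams | None = None
) -> tuple[bool, int | None, int | None]:
    """Offset-tolerant exact match of a read against one reference.

    Tries every ungapped placement with |offset_5p| <= 2; the 3' offset is
    then fixed by the length difference and must satisfy |offset_3p| <= 4.
    Every overlapping position must be identical.  Among qualifying
    placements the one minimizing |offset_5p| then |offset_3p| wins.
    """
    params = params or AlignmentParams()
    ref_seq = ref.sequence if isinstance(ref, MatureReference) else ref
    placements = []
    for o5 in range(-params.max_5p_offset, params.max_5p_offset + 1):
        o3 = o5 + len(read) - len(ref_seq)
        if abs(o3) > params.max_3p_offset:
            continue
        if _overlap_identical(read, ref_seq, o5):
            placements.append((abs(o5), abs(o3), o5, o3))
    if not placements:
        return (False, None, None)
    placements.sort()
    _, _, o5, o3 = placements[0]
    return (True, o5, o3)


def _overlap_identical(read: str, ref: str, o5: int) -> bool:
    """True iff read placed at 5' offset ``o5`` matches ref on the overlap."""
    if o5 >= 0:
        ov = min(len(read), len(ref) - o5)
        if ov <= 0:
            return False
        return read[:ov] == ref[o5 : o5 + ov]
    start = -o5
    ov = min(len(ref), len(read) - start)
    if ov <= 0:
        return False
    return read[start : start + ov] == ref[:ov]


def prefix10_candidates(
    read: str,
    refs: list[MatureReference],
    params: AlignmentParams | None = None,
) -> list[MatureReference]:
    """References whose first ``prefix_len`` nt equal the read's."""
    params = params or AlignmentParams()
    k = params.prefix_len
    if len(read) < k:
        return []
    prefix = read[:k]
    return [r for r in refs if r.sequence[:k] == prefix]


def longest_run(read: str, ref: str) -> int:
    """Longest contiguous identical block, 5'-anchored, ungapped."""
    best = run = 0
    for x, y in zip(read, ref):
        if x == y:
            run += 1
            if run > best:
                best = run
        else:
            run = 0
    return best


class ReferenceIndex:
    """Hash index over a reference set for fast tier-1/prefix lookups."""

    def __init__(self, refs: list[MatureReference], params: AlignmentParams):
        self.refs = list(refs)
        self.params = params
        k = params.prefix_len
        # prefix -> refs, for tier-2/3 candidacy and negative 5' offsets
        self.by_prefix: dict[str, list[MatureReference]] = defaultdict(list)
        # shifted k-mer -> (ref, o5>=0) placements for tier 1
        self.by_shifted: dict[str, list[tuple[MatureReference, int]]] = defaultdict(list)
        for ref in self.refs:
            self.by_prefix[ref.sequence[:k]].append(ref)
            for o5 in range(0, params.max_5p_offset + 1):
                key = ref.sequence[o5 : o5 + k]
                if len(key) == k:
                    self.by_shifted[key].append((ref, o5))

    def tier1_candidates(self, read: str) -> list[tuple[MatureReference, int]]:
        """(ref, offset_5p) placements whose aligned k-mer matches the read."""
        k = self.params.prefix_len
        out = list(self.by_shifted.get(read[:k], ()))
        for o5 in range(1, self.params.max_5p_offset + 1):
            key = read[o5 : o5 + k]
            if len(key) == k:
                out.extend((ref, -o5) for ref in self.by_prefix.get(key, ()))
        return out

    def prefix_candidates(self, read: str) -> list[MatureReference]:
        k = self.params.prefix_len
        if len(read) < k:
            return []
        return self.by_prefix.get(read[:k], [])


def classify_read(
    read: SmallRNARead | str,
    refs: list[MatureReference],
    params: AlignmentParams | None = None,
    index: ReferenceIndex | None = None,
) -> AnnotationResult:
    """Run the annotation cascade on one 18-25 nt read.

    Tie-breaking across references: highest tier first, then the highest
    Smith-Waterman score (longest run for tier 2), then the smallest
    |offset_5p| + |offset_3p|, then the lexicographically smallest id.
    """
    params = params or AlignmentParams()
    if isinstance(read, str):
        read = SmallRNARead(sequence=read)
    seq = read.sequence
    if not 18 <= len(seq) <= 25:
        raise ValueError(f"classify_read requires 18-25 nt reads, got {len(seq)} nt")

    def result(**kw) -> AnnotationResult:
        return AnnotationResult(sequence=seq, count=read.count, tissue=read.tissue, **kw)

    # tier 1 over all references
    if index is not None:
        t1_pairs = index.tier1_candidates(seq)
        hits = []
        for ref, o5 in t1_pairs:
            o3 = o5 + len(seq) - len(ref.sequence)
            if abs(o3) <= params.max_3p_offset and _overlap_identical(seq, ref.sequence, o5):
                hits.append((abs(o5) + abs(o3), ref.id, o5, o3, ref))
    else:
        hits = []
        for ref in refs:
            ok, o5, o3 = tier1_match(seq, ref, params)
            if ok:
                hits.append((abs(o5) + abs(o3), ref.id, o5, o3, ref))
    if hits:
        hits.sort(key=lambda h: (h[0], h[1]))
        _, _, o5, o3, ref = hits[0]
        return result(
            tier=TIER1, matched_id=ref.id, family=fru_family(ref.id),
            offset_5p=o5, offset_3p=o3,
        )

    # prefix-restricted tiers
    candidates = (
        index.prefix_candidates(seq) if index is not None
        else prefix10_candidates(seq, refs, params)
    )
    if not candidates:
        return result(tier=UNANNOTATED)

    runs = sorted(
        ((longest_run(seq, r.sequence), r) for r in candidates),
        key=lambda t: (-t[0], t[1].id),
    )
    best_run, best_run_ref = runs[0]
    if best_run >= params.min_contiguous:
        return result(
            tier=TIER2, matched_id=best_run_ref.id, family=fru_family(best_run_ref.id),
            offset_5p=0, offset_3p=len(seq) - len(best_run_ref.sequence),
            longest_run=best_run,
        )

    scores = sorted(
        ((sw_score(seq, r.sequence, params), r) for r in candidates),
        key=lambda t: (-t[0], t[1].id),
    )
    best_sw, best_sw_ref = scores[0]
    tier = TIER3 if best_sw >= params.sw_threshold else PUTATIVE
    return result(
        tier=tier, matched_id=best_sw_ref.id, family=fru_family(best_sw_ref.id),
        offset_5p=0, offset_3p=len(seq) - len(best_sw_ref.sequence),
        longest_run=longest_run(seq, best_sw_ref.sequence), sw_score=best_sw,
    )


def annotate_library(
    reads: list[SmallRNARead],
    refs: list[MatureReference],
    params: AlignmentParams | None = None,
) -> tuple[list[AnnotationResult], dict[str, int]]:
    """Classify every 18-25 nt collapsed read; returns results + tier totals.

    Tier totals are weighted by collapse multiplicity and sum to the
    18-25 nt read total.  Reads outside 18-25 nt are ignored.
    """
    params = params or AlignmentParams()
    if not refs:
        logger.warning("annotate_library: empty reference set; all reads unannotated")
    index = ReferenceIndex(refs, params) if refs else None
    results: list[AnnotationResult] = []
    tier_counts: dict[str, int] = {t: 0 for t in TIERS}
    for read in reads:
        if not 18 <= len(read.sequence) <= 25:
            continue
        if index is None:
            res = AnnotationResult(
                sequence=read.sequence, count=read.count, tissue=read.tissue,
                tier=UNANNOTATED,
            )
        else:
            res = classify_read(read, refs, params, index=index)
        results.append(res)
        tier_counts[res.tier] += res.count
    return results, tier_counts
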