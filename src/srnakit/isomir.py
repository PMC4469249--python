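"""IsomiR analysis: terminal-variant taxonomy, major isomiRs, seed shifts.

IsomiRs are sequence variants of one mature miRNA differing at the 5'
and/or 3' terminus.  Variation is defined on reference-relative end
offsets, not on raw sequence comparison: a 5' offset shift moves the seed
(positions 2-8) and therefore potentially the target repertoire, which is
what the seed-shift report surfaces.  Internal substitutions with unchanged
offsets are excluded from the terminal taxonomy and only logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotate import MIRNA_TIERS, AnnotationResult

logger = logging.getLogger("srnakit.isomir")

IDENTICAL = "identical"
VAR_3P = "3p_only"
VAR_5P = "5p_only"
VAR_BOTH = "both"
VARIANT_CLASSES = (IDENTICAL, VAR_3P, VAR_5P, VAR_BOTH)


@dataclass(slots=True)
class IsomiRVariant:
    sequence: str
    count: int
    offset_5p: int
    offset_3p: int


@dataclass(slots=True)
class IsomiRGroup:
    """All variant reads assigned to one parent family in one tissue."""

    parent: str
    tissue: str
    variants: list[IsomiRVariant]

    @property
    def major(self) -> IsomiRVariant:
        return major_isomir(self.variants)

    @property
    def total(self) -> int:
        return sum(v.count for v in self.variants)


def group_by_parent(
    results: Sequence[AnnotationResult],
) -> dict[tuple[str, str], IsomiRGroup]:
    """Group tier 1-3 reads by (tissue, parent family).

    Every tier 1-3 read lands in exactly one group, keyed by the family of
    its matched reference.
    """
    groups: dict[tuple[str, str], IsomiRGroup] = {}
    for res in results:
        if res.tier not in MIRNA_TIERS:
            continue
        if res.family is None or res.offset_5p is None or res.offset_3p is None:
            raise ValueError("tier 1-3 annotation lacks family/offsets")
        key = (res.tissue, res.family)
        if key not in groups:
            groups[key] = IsomiRGroup(parent=res.family, tissue=res.tissue, variants=[])
        groups[key].variants.append(
            IsomiRVariant(res.sequence, res.count, res.offset_5p, res.offset_3p)
        )
    return groups


def major_isomir(variants: Sequence[IsomiRVariant]) -> IsomiRVariant:
    """Elect the most abundant variant; ties go to the longer, then
    lexicographically smaller, sequence."""
    if not variants:
        raise ValueError("cannot elect a major isomiR from an empty group")
    return min(variants, key=lambda v: (-v.count, -len(v.sequence), v.sequence))


def classify_variant(variant: IsomiRVariant, major: IsomiRVariant) -> str:
    """Terminal-variation class of a variant relative to the major isomiR.

    Compares reference-relative end offsets only; a sequence difference
    with equal offsets (an internal substitution) is 'identical' at the
    termini.
    """
    d5 = variant.offset_5p != major.offset_5p
    d3 = variant.offset_3p != major.offset_3p
    if d5 and d3:
        return VAR_BOTH
    if d5:
        return VAR_5P
    if d3:
        return VAR_3P
    return IDENTICAL


def class_fractions(
    groups: Mapping[tuple[str, str], IsomiRGroup],
    per_tissue: bool = False,
) -> pd.Series | pd.DataFrame:
    """Count-weighted fractions of the four terminal classes.

    Classification is relative to each group's own (per-tissue) major
    isomiR.  Internal variants (same offsets, different sequence from the
    major) are logged.  With ``per_tissue=True`` a tissue x class
    DataFrame is returned, otherwise one population-level Series.
    """
    counts: dict[str, dict[str, int]] = {}
    internal = 0
    for group in groups.values():
        major = group.major
        row = counts.setdefault(group.tissue, {c: 0 for c in VARIANT_CLASSES})
        for v in group.variants:
            cls = classify_variant(v, major)
            row[cls] += v.count
            if cls == IDENTICAL and v.sequence != major.sequence:
                internal += v.count
    if internal:
        logger.info("isomiR internal variants (same offsets, different sequence): %d reads", internal)
    table = pd.DataFrame.from_dict(counts, orient="index").reindex(
        columns=list(VARIANT_CLASSES), fill_value=0
    )
    if per_tissue:
        sums = table.sum(axis=1)
        return table.div(sums.where(sums > 0, other=1.0), axis=0)
    totals = table.sum(axis=0).astype(float)
    grand = totals.sum()
    return totals / grand if grand > 0 else totals


def seed_of(sequence: str) -> str:
    """The 7-nt seed: positions 2-8 from the 5' end (1-based, inclusive)."""
    if len(sequence) < 8:
        raise ValueError(f"sequence of {len(sequence)} nt has no complete seed")
    return sequence[1:8]


def seed_shift_report(
    groups: Mapping[tuple[str, str], IsomiRGroup],
    totals_18_25: Mapping[str, int],
) -> pd.DataFrame:
    """Families whose per-tissue major isomiR seed differs between tissues.

    Requires at least two tissues.  For each reported family every tissue
    in which it was observed gets a row (family, tissue, major_sequence,
    seed, rpm); families with a single common seed everywhere are excluded.
    Rows are ordered by family then tissue.
    """
    tissues = {t for (t, _f) in groups}
    if len(tissues) < 2:
        return pd.DataFrame(
            columns=["family", "tissue", "major_sequence", "seed", "rpm"]
        )
    by_family: dict[str, list[tuple[str, IsomiRGroup]]] = {}
    for (tissue, family), group in groups.items():
        by_family.setdefault(family, []).append((tissue, group))
    rows = []
    for family in sorted(by_family):
        entries = sorted(by_family[family])
        seeds = {seed_of(g.major.sequence) for _t, g in entries}
        if len(seeds) < 2:
            continue
        for tissue, group in entries:
            major = group.major
            total = totals_18_25[tissue]
            rows.append(
                {
                    "family": family,
                    "tissue": tissue,
                    "major_sequence": major.sequence,
                    "seed": seed_of(major.sequence),
                    "rpm": major.count / total * 1e6,
                }
            )
    return pd.DataFrame(rows, columns=["family", "tissue", "major_sequence", "seed", "rpm"])
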