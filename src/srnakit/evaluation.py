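"""Benchmark scoring of the pipeline against synthetic ground truth.

Given a simulated dataset (whose truth tables record each read's origin,
intended annotation tier and end offsets) and the corresponding pipeline
output, these helpers compute recovery errors: tier-composition error,
planted fold-change error, and isomiR-class-fraction error.  Expected
values are derived purely from the truth tables, never from the classifier.
"""

from __future__ import annotations

import pandas as pd

from .annotate import MIRNA_TIERS, TIERS, AlignmentParams
from .io_formats import SmallRNARead
from .isomir import VARIANT_CLASSES, class_fractions, group_by_parent
from .pipeline import ProcessedLibrary, process_library
from .profiling import category_proportions, expression_matrix
from .synthetic_data import SimulatedDataset

TIER_NAME_MAP = {
    "tier1": "miRNA_tier1",
    "tier2": "miRNA_tier2",
    "tier3": "miRNA_tier3",
    "putative": "putative_miRNA",
}


def process_dataset(
    dataset: SimulatedDataset, params: AlignmentParams | None = None
) -> dict[str, ProcessedLibrary]:
    """Run the full pipeline on every simulated tissue library."""
    out = {}
    for tissue, (records, _truth) in dataset.libraries.items():
        raw = [
            SmallRNARead(sequence=seq, tissue=tissue, mean_quality=40.0)
            for _rid, seq, _q in records
        ]
        out[tissue] = process_library(
            raw, tissue, dataset.config.adapter, dataset.refs, params
        )
    return out


def _window(truth: pd.DataFrame) -> pd.DataFrame:
    return truth[truth.insert_length.between(18, 25)]


def expected_tier_fractions(truth: pd.DataFrame) -> pd.Series:
    """Tier composition implied by the truth table for the 18-25 nt window.

    MiRNA-origin reads carry their intended tier; background reads in the
    window are expected to stay unannotated (an accidental 10-nt prefix
    match has probability ~n_refs x 4^-10 per read).
    """
    window = _window(truth)
    counts = pd.Series(0.0, index=list(TIERS))
    for row in window.itertuples():
        if row.origin == "mirna":
            counts[TIER_NAME_MAP[row.intended_tier]] += 1
        else:
            counts["unannotated"] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def observed_tier_fractions(library: ProcessedLibrary) -> pd.Series:
    return category_proportions(library.results)


def tier_composition_error(
    library: ProcessedLibrary, truth: pd.DataFrame
) -> float:
    """Largest absolute per-tier deviation, in percentage points."""
    expected = expected_tier_fractions(truth)
    observed = observed_tier_fractions(library)
    return float((observed - expected).abs().max() * 100)


def truth_rpm(truth: pd.DataFrame, family: str) -> float:
    """Truth-side RPM of one family: tier 1-3 intended reads over the
    18-25 nt window total."""
    window = _window(truth)
    total = len(window)
    mirna = window[
        (window.origin == "mirna")
        & (window.family == family)
        & (window.intended_tier != "putative")
    ]
    return len(mirna) / total * 1e6


def planted_fold_errors(
    processed: dict[str, ProcessedLibrary],
    truths: dict[str, pd.DataFrame],
    planted: list[tuple[str, str, str]],
) -> dict[str, tuple[float, float, float]]:
    """Per planted (family, tissue_high, tissue_low): observed fold,
    truth fold, relative error."""
    tables = expression_matrix({t: lib.results for t, lib in processed.items()})
    rpm = tables["rpm"]
    out = {}
    for family, high, low in planted:
        observed = float(rpm.loc[family, high]) / float(rpm.loc[family, low])
        expected = truth_rpm(truths[high], family) / truth_rpm(truths[low], family)
        rel_err = abs(observed - expected) / expected
        out[family] = (observed, expected, rel_err)
    return out


def expected_isomir_fractions(truths: dict[str, pd.DataFrame]) -> pd.Series:
    """Terminal-class fractions implied by the truth offsets.

    Within each (tissue, family) group of tier 1-3 intended reads, the
    most frequent insert sequence (ties: longer, then lexicographically
    smaller) defines the major isomiR; every read's sampled offsets are
    classified against the major's offsets.
    """
    counts = pd.Series(0.0, index=list(VARIANT_CLASSES))
    for tissue, truth in truths.items():
        window = _window(truth)
        mirna = window[(window.origin == "mirna") & (window.intended_tier != "putative")]
        for _family, grp in mirna.groupby("family"):
            per_variant = (
                grp.groupby("insert")
                .agg(n=("read_id", "size"), o5=("offset_5p", "first"), o3=("offset_3p", "first"))
                .reset_index()
            )
            per_variant["length"] = per_variant["insert"].str.len()
            per_variant = per_variant.sort_values(
                by=["n", "length", "insert"], ascending=[False, False, True]
            )
            major = per_variant.iloc[0]
            for row in per_variant.itertuples():
                d5 = row.o5 != major.o5
                d3 = row.o3 != major.o3
                cls = "both" if (d5 and d3) else "5p_only" if d5 else "3p_only" if d3 else "identical"
                counts[cls] += row.n
    total = counts.sum()
    return counts / total if total > 0 else counts


def observed_isomir_fractions(processed: dict[str, ProcessedLibrary]) -> pd.Series:
    results = [r for lib in processed.values() for r in lib.results]
    return class_fractions(group_by_parent(results))


def exclusion_zone_counts(processed: dict[str, ProcessedLibrary]) -> int:
    """Number of post-trim reads with length 32-34 across all tissues."""
    return sum(
        read.count
        for lib in processed.values()
        for read in lib.collapsed
        if 32 <= len(read.sequence) <= 34
    )
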