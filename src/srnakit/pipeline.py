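"""End-to-end orchestration: trim -> annotate -> profile -> isomiR ->
differential expression -> size-class composition.

This module is the programmatic driver behind the ``run-all`` CLI
subcommand; each stage logs the read counts entering and leaving it so the
run log forms a conservation ledger (input = kept + dropped at every
stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import annotate, diffexpr, io_formats, isomir, preprocess, profiling, size_classes
from .annotate import AlignmentParams, AnnotationResult
from .io_formats import MatureReference, SmallRNARead

logger = logging.getLogger("srnakit.pipeline")

CONFIG_KEYS = {
    "reference", "repeats", "manifest", "adapter", "min_overlap", "min_mean_q",
    "alignment", "diffexpr", "min_exact",
}
ALIGNMENT_KEYS = {
    "match_score", "mismatch_score", "gap_open", "gap_extend", "sw_threshold",
    "min_contiguous", "prefix_len", "max_5p_offset", "max_3p_offset", "use_gaps",
}
DIFFEXPR_KEYS = {"tissue_a", "tissue_b", "min_fold", "min_rpm", "top_n"}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(slots=True)
class StageCounts:
    stage: str
    entered: int
    kept: int

    @property
    def dropped(self) -> int:
        return self.entered - self.kept


@dataclass(slots=True)
class ProcessedLibrary:
    """One tissue's reads after preprocessing plus its annotation results."""

    tissue: str
    collapsed: list[SmallRNARead]          # all trimmed lengths, collapsed
    results: list[AnnotationResult]        # 18-25 nt annotation calls
    tier_counts: dict[str, int]
    stages: list[StageCounts] = field(default_factory=list)

    @property
    def total_18_25(self) -> int:
        return sum(r.count for r in self.results)


def process_library(
    raw_reads: list[SmallRNARead],
    tissue: str,
    adapter: str,
    refs: list[MatureReference],
    params: AlignmentParams | None = None,
    min_overlap: int = 4,
    min_mean_q: int = 20,
) -> ProcessedLibrary:
    """Quality-filter, trim, collapse and annotate one tissue library."""
    params = params or AlignmentParams()
    stages: list[StageCounts] = []
    n_raw = sum(r.count for r in raw_reads)

    filtered = preprocess.quality_filter(raw_reads, min_mean_q=min_mean_q)
    stages.append(StageCounts("quality_filter", n_raw, sum(r.count for r in filtered)))

    trimmed = []
    for read in filtered:
        res = preprocess.trim_adapter(read.sequence, adapter, min_overlap=min_overlap)
        if res.trimmed_length > 0:
            trimmed.append(
                SmallRNARead(sequence=res.sequence, count=read.count, tissue=tissue)
            )
    stages.append(StageCounts("trim_adapter", stages[-1].kept, sum(r.count for r in trimmed)))

    collapsed = preprocess.collapse(trimmed)
    stages.append(StageCounts("collapse", stages[-1].kept, sum(r.count for r in collapsed)))

    window = preprocess.select_length(collapsed, 18, 25)
    stages.append(StageCounts("select_18_25", stages[-1].kept, sum(r.count for r in window)))

    results, tier_counts = annotate.annotate_library(window, refs, params)
    for st in stages:
        logger.info(
            "[%s] %s: entered=%d kept=%d dropped=%d",
            tissue, st.stage, st.entered, st.kept, st.dropped,
        )
    return ProcessedLibrary(
        tissue=tissue, collapsed=collapsed, results=results,
        tier_counts=tier_counts, stages=stages,
    )


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Reject unknown keys and missing files before any work is done."""
    unknown = set(config) - CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for required in ("reference", "manifest", "adapter"):
        if required not in config:
            raise ConfigError(f"config key {required!r} is required")
    for path_key in ("reference", "repeats", "manifest"):
        if path_key in config and not Path(config[path_key]).exists():
            raise ConfigError(f"{path_key} file not found: {config[path_key]}")
    alignment = config.get("alignment", {})
    bad = set(alignment) - ALIGNMENT_KEYS
    if bad:
        raise ConfigError(f"unknown alignment keys: {sorted(bad)}")
    de = config.get("diffexpr", {})
    bad = set(de) - DIFFEXPR_KEYS
    if bad:
        raise ConfigError(f"unknown diffexpr keys: {sorted(bad)}")
    return dict(config)


def _annotations_frame(libraries: Mapping[str, ProcessedLibrary]) -> pd.DataFrame:
    rows = []
    for lib in libraries.values():
        for r in lib.results:
            rows.append({
                "sequence": r.sequence, "count": r.count, "tissue": r.tissue,
                "tier": r.tier, "matched_id": r.matched_id or "",
                "family": r.family or "",
                "offset_5p": r.offset_5p, "offset_3p": r.offset_3p,
                "longest_run": r.longest_run, "sw_score": r.sw_score,
            })
    return pd.DataFrame(rows, columns=[
        "sequence", "count", "tissue", "tier", "matched_id", "family",
        "offset_5p", "offset_3p", "longest_run", "sw_score",
    ])


def run_all(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Path]:
    """Run every stage on every manifest sample; write all result tables.

    Stage failures abort with a stage-named error; tables already written
    are retained.  Returns the mapping of output names to paths.
    """
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("srnakit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("parameters: %s", dict(config))

    outputs: dict[str, Path] = {"log": log_path}
    try:
        params = AlignmentParams(**config.get("alignment", {}))
        refs = io_formats.load_reference(config["reference"])
        manifest = io_formats.load_manifest(config["manifest"])

        libraries: dict[str, ProcessedLibrary] = {}
        for sample_path, tissue in manifest:
            try:
                raw = io_formats.load_reads(sample_path, tissue=tissue)
                libraries[tissue] = process_library(
                    raw, tissue, config["adapter"], refs, params,
                    min_overlap=int(config.get("min_overlap", 4)),
                    min_mean_q=int(config.get("min_mean_q", 20)),
                )
            except Exception as exc:
                raise RuntimeError(f"stage trim/annotate failed for {tissue}: {exc}") from exc

        def write(name: str, df: pd.DataFrame) -> None:
            path = out / name
            io_formats.write_table(df, path)
            outputs[name] = path

        write("annotations.tsv", _annotations_frame(libraries))

        results_by_tissue = {t: lib.results for t, lib in libraries.items()}
        try:
            tables = profiling.expression_matrix(results_by_tissue)
            write("expression_rpm.tsv", tables["rpm"].reset_index(names="mirna_id"))
            write("expression_raw.tsv", tables["raw"].reset_index(names="mirna_id"))
            write("putative_rpm.tsv", tables["putative_rpm"].reset_index(names="mirna_id"))
            size_rows = []
            for tissue, lib in libraries.items():
                dist = profiling.size_distribution(lib.collapsed, tissue)
                for length, value in dist.items():
                    size_rows.append({"tissue": tissue, "length": length,
                                      "reads_per_million": value})
            write("size_distribution.tsv", pd.DataFrame(size_rows))
            cat_rows = []
            for tissue, lib in libraries.items():
                props = profiling.category_proportions(lib.results)
                row = {"tissue": tissue, **{k: float(v) for k, v in props.items()}}
                cat_rows.append(row)
            write("category_proportions.tsv", pd.DataFrame(cat_rows))
        except Exception as exc:
            raise RuntimeError(f"stage profile failed: {exc}") from exc

        try:
            all_results = [r for lib in libraries.values() for r in lib.results]
            groups = isomir.group_by_parent(all_results)
            totals = {t: lib.total_18_25 for t, lib in libraries.items()}
            classes = isomir.class_fractions(groups, per_tissue=True)
            write("isomir_classes.tsv", classes.reset_index(names="tissue"))
            major_rows = []
            for (tissue, family), group in sorted(groups.items()):
                major = group.major
                major_rows.append({
                    "family": family, "tissue": tissue,
                    "major_sequence": major.sequence, "seed": isomir.seed_of(major.sequence),
                    "count": major.count,
                })
            write("major_isomirs.tsv", pd.DataFrame(
                major_rows, columns=["family", "tissue", "major_sequence", "seed", "count"]))
            write("seed_shifts.tsv", isomir.seed_shift_report(groups, totals))
        except Exception as exc:
            raise RuntimeError(f"stage isomir failed: {exc}") from exc

        try:
            de_cfg = config.get("diffexpr", {})
            tissues = list(libraries)
            tissue_a = de_cfg.get("tissue_a", tissues[0])
            tissue_b = de_cfg.get("tissue_b", tissues[min(1, len(tissues) - 1)])
            if tissue_a != tissue_b:
                tables = profiling.expression_matrix(results_by_tissue)
                de = diffexpr.differential_table(
                    tables["rpm"], tissue_a, tissue_b,
                    min_fold=float(de_cfg.get("min_fold", 1.5)),
                    min_rpm=float(de_cfg.get("min_rpm", 1000)),
                    top_n=int(de_cfg.get("top_n", 5)),
                )
                write(f"diffexpr_{tissue_a}_gt_{tissue_b}.tsv", de["a_greater"])
                write(f"diffexpr_{tissue_b}_gt_{tissue_a}.tsv", de["b_greater"])
        except Exception as exc:
            raise RuntimeError(f"stage diffexpr failed: {exc}") from exc

        try:
            repeats = io_formats.load_repeats(config["repeats"]) if "repeats" in config else []
            index = size_classes.RepeatIndex(repeats, min_exact=int(config.get("min_exact", 20)))
            comp_rows = []
            for tissue, lib in libraries.items():
                summary = size_classes.composition_summary(
                    lib.collapsed, lib.results, index, tissue=tissue
                )
                row = {"tissue": tissue,
                       **{k: float(v) for k, v in summary.fractions.items()},
                       "putative_pirna_fraction": summary.putative_pirna_fraction}
                row.update({f"pirna_first_{nt}": float(summary.pirna_first_nt[nt])
                            for nt in "ACGT"})
                comp_rows.append(row)
            write("composition.tsv", pd.DataFrame(comp_rows))
        except Exception as exc:
            raise RuntimeError(f"stage classify-other failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outputs
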