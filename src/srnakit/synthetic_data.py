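"""Synthetic small RNA libraries with per-read ground truth.

The generator emulates the statistical structure of deep-sequenced fish
tissue libraries: fixed 35-nt raw reads consisting of an insert plus a 3'
adapter fill; somatic tissues dominated by ~22-nt miRNA reads with mostly
3'-terminal isomiR variation and very rare 5' variation; gonadal tissues
dominated by 26-31 nt repeat-derived reads (putative piRNAs, mode 27 nt);
and a uniform-random background.  Every simulated read carries a truth
record (origin, reference, end offsets, intended annotation tier, insert
length), so each pipeline stage can be scored against ground truth.

MiRNA-origin reads are constructed to land in a chosen annotation tier:

* tier 1 — sampled end offsets, no substitutions;
* tier 2 — one substitution at an anchored position >= 17, which leaves a
  contiguous identical run of >= 16 nt;
* tier 3 — one substitution at positions 11-16, breaking the 16-nt run
  while the local-alignment score stays >= 70;
* putative — the 10-nt prefix kept intact, every remaining templated
  position mismatched (a rejection guard keeps the alignment score < 70).

This makes per-read tier ground truth exact by construction rather than
an analytic approximation.  3'-extension nucleotides beyond the mature
reference are drawn uniformly at random: templated extension would need
hairpin context, which mature-only references cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AlignmentParams, fru_family, longest_run, sw_score
from .io_formats import MatureReference, write_fastq
from .published_tables import PLANTED_PARENTS

NT = "ACGT"
RAW_LENGTH = 35
DEFAULT_ADAPTER = "CGCCTTGGCCGTACAGCAG"

TIER_NAMES = ("tier1", "tier2", "tier3", "putative")

# putative piRNA insert lengths 26-31, mode 27
PIRNA_LENGTHS = (26, 27, 28, 29, 30, 31)
PIRNA_LENGTH_WEIGHTS = (0.10, 0.35, 0.22, 0.15, 0.10, 0.08)


def default_offset_table() -> dict[tuple[int, int], float]:
    """Isomir end-offset distribution: ~50% canonical ends, ~49% 3'-only
    variation, ~1% with any 5' shift (split between 5'-only and both)."""
    table: dict[tuple[int, int], float] = {(0, 0): 0.50}
    for o3, p in ((1, 0.13), (2, 0.07), (3, 0.03), (4, 0.015)):
        table[(0, o3)] = p
        table[(0, -o3)] = p
    table[(1, 0)] = 0.002
    table[(-1, 0)] = 0.002
    table[(2, 0)] = 0.0005
    table[(-2, 0)] = 0.0005
    table[(1, 1)] = 0.002
    table[(-1, -1)] = 0.002
    table[(1, -1)] = 0.0005
    table[(-1, 1)] = 0.0005
    return table


@dataclass(slots=True)
class TissueProfile:
    """Mixture and abundance structure of one simulated tissue library."""

    library_size: int
    length_mode: str  # 'somatic' | 'gonadal'
    mirna_fraction: float
    repeat_fraction: float
    # expression multipliers on the shared base weights, by reference id
    expression_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_mode not in {"somatic", "gonadal"}:
            raise ValueError(f"unknown length_mode {self.length_mode!r}")
        if self.mirna_fraction + self.repeat_fraction > 1:
            raise ValueError("mirna_fraction + repeat_fraction must be <= 1")


@dataclass(slots=True)
class SimulationConfig:
    n_mirnas: int = 60
    mature_length_range: tuple[int, int] = (18, 25)
    tissue_profiles: dict[str, TissueProfile] = field(default_factory=dict)
    isomir_offsets: dict[tuple[int, int], float] = field(default_factory=default_offset_table)
    tier_mix: dict[str, float] = field(
        default_factory=lambda: {"tier1": 0.40, "tier2": 0.49, "tier3": 0.10, "putative": 0.01}
    )
    substitution_rate: float = 0.0  # extra uncontrolled per-nt noise
    adapter: str = DEFAULT_ADAPTER
    n_repeats: int = 3
    repeat_length: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        total = sum(self.isomir_offsets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isomir_offsets probabilities sum to {total}, not 1")
        if abs(sum(self.tier_mix.values()) - 1.0) > 1e-9:
            raise ValueError("tier_mix probabilities must sum to 1")


def default_config(library_size: int = 100_000, seed: int = 0) -> SimulationConfig:
    """Three-tissue study layout: two somatic muscles and one gonad.

    Somatic libraries are 75% miRNA-derived, 5% repeat-derived and 20%
    random background; the gonadal library is 8% miRNA, 70% repeat-derived
    26-31 nt reads and 22% background.  Differential expression is planted
    through tissue multipliers on three named references.
    """
    return SimulationConfig(
        rng_seed=seed,
        tissue_profiles={
            "fast_muscle": TissueProfile(
                library_size=library_size, length_mode="somatic",
                mirna_fraction=0.75, repeat_fraction=0.05,
                expression_overrides={"dre-miR-206-3p": 25.0},
            ),
            "heart": TissueProfile(
                library_size=library_size, length_mode="somatic",
                mirna_fraction=0.75, repeat_fraction=0.05,
                expression_overrides={"dre-miR-499-5p": 20.0},
            ),
            "testes": TissueProfile(
                library_size=library_size, length_mode="gonadal",
                mirna_fraction=0.08, repeat_fraction=0.70,
                expression_overrides={"dre-miR-202-5p": 30.0},
            ),
        },
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, seq: str, pos: int) -> str:
    choices = [c for c in NT if c != seq[pos]]
    return seq[:pos] + choices[rng.integers(0, 3)] + seq[pos + 1 :]


def make_reference(
    config: SimulationConfig,
) -> tuple[list[MatureReference], list[tuple[str, str]]]:
    """Random mature references with pairwise-distinct 10-nt prefixes, the
    planted worked-example parents, three named planted references for
    differential expression, and a repeat-element set."""
    rng = np.random.default_rng([config.rng_seed, 0])
    refs: list[MatureReference] = []
    prefixes: set[str] = set()
    for rid, seq in PLANTED_PARENTS.items():
        refs.append(MatureReference(id=rid, sequence=seq))
        prefixes.add(seq[:10])
    lo, hi = config.mature_length_range
    lengths = [n for n in (20, 21, 22, 23, 24) if lo <= n <= hi] or [max(lo, 18)]
    weights = {20: 0.15, 21: 0.20, 22: 0.30, 23: 0.20, 24: 0.15}
    probs = np.array([weights.get(n, 0.2) for n in lengths], dtype=float)
    probs /= probs.sum()
    named = ["dre-miR-206-3p", "dre-miR-499-5p", "dre-miR-202-5p"]
    ids = named + [f"dre-miR-{7000 + i}-5p" for i in range(config.n_mirnas - len(named))]
    for rid in ids[: config.n_mirnas]:
        while True:
            # the planted high-abundance references are canonical 22-mers,
            # keeping the somatic length mode at 22 nt as dominant muscle
            # miRNAs do in real libraries
            n = 22 if rid in named and 22 in lengths else int(rng.choice(lengths, p=probs))
            seq = _random_seq(rng, n)
            if seq[:10] not in prefixes:
                prefixes.add(seq[:10])
                refs.append(MatureReference(id=rid, sequence=seq))
                break
    repeats = [
        (f"repeat_{i}", _random_seq(rng, config.repeat_length))
        for i in range(config.n_repeats)
    ]
    return refs, repeats


def expression_weights(
    config: SimulationConfig, refs: list[MatureReference], tissue: str
) -> np.ndarray:
    """Per-tissue normalized expression weights over the reference set.

    A shared log-normal base abundance (planted references get a fixed
    elevated base so fold changes are measured on well-covered miRNAs) is
    scaled by the tissue's multipliers and normalized.
    """
    rng = np.random.default_rng([config.rng_seed, 99])
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(refs))
    elevated = set(PLANTED_PARENTS) | {"dre-miR-206-3p", "dre-miR-499-5p", "dre-miR-202-5p"}
    for i, ref in enumerate(refs):
        if ref.id in elevated:
            base[i] = 2.0
    overrides = config.tissue_profiles[tissue].expression_overrides
    mult = np.array([overrides.get(ref.id, 1.0) for ref in refs])
    w = base * mult
    return w / w.sum()


def _conditional_offsets(
    table: dict[tuple[int, int], float]
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Offset table conditioned on offset_5p == 0 (prefix-anchored tiers)."""
    pairs = [(o5, o3) for (o5, o3) in table if o5 == 0]
    probs = np.array([table[p] for p in pairs], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("isomir_offsets has no mass on offset_5p == 0")
    return pairs, probs / probs.sum()


def _build_mirna_insert(
    rng: np.random.Generator,
    ref: MatureReference,
    tier: str,
    offsets: tuple[list[tuple[int, int]], np.ndarray],
    cond_offsets: tuple[list[tuple[int, int]], np.ndarray],
    params: AlignmentParams,
) -> tuple[str, int, int]:
    ref_seq = ref.sequence
    if tier == "tier1":
        pairs, probs = offsets
        o5, o3 = pairs[rng.choice(len(pairs), p=probs)]
    else:
        pairs, probs = cond_offsets
        for _ in range(100):
            o5, o3 = pairs[rng.choice(len(pairs), p=probs)]
            if 18 <= len(ref_seq) + o3 <= 25:
                break
    core = ref_seq
    if o5 > 0:
        core = core[o5:]
    elif o5 < 0:
        core = _random_seq(rng, -o5) + core
    if o3 < 0:
        core = core[:o3]
    elif o3 > 0:
        core = core + _random_seq(rng, o3)
    if tier == "tier1":
        return core, o5, o3
    anchored = min(len(core), len(ref_seq))  # o5 == 0 here
    if tier == "tier2":
        p = int(rng.integers(17, anchored + 1))  # 1-based position >= 17
        return _mutate(rng, core, p - 1), o5, o3
    if tier == "tier3":
        p = int(rng.integers(11, min(16, anchored) + 1))
        return _mutate(rng, core, p - 1), o5, o3
    # putative: intact 10-nt prefix, fully mismatching templated tail
    for _ in range(50):
        tail = []
        for i in range(10, len(core)):
            if i < len(ref_seq):
                choices = [c for c in NT if c != ref_seq[i]]
                tail.append(choices[rng.integers(0, 3)])
            else:
                tail.append(NT[rng.integers(0, 4)])
        candidate = core[:10] + "".join(tail)
        if (
            longest_run(candidate, ref_seq) < params.min_contiguous
            and sw_score(candidate, ref_seq, params) < params.sw_threshold
        ):
            return candidate, o5, o3
    raise RuntimeError("could not construct a putative-tier insert")


def simulate_library(
    config: SimulationConfig,
    tissue: str,
    refs: list[MatureReference],
    repeats: list[tuple[str, str]],
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one tissue's raw 35-nt FASTQ records plus the truth table.

    Each insert is concatenated with the 3' adapter and random fill, then
    truncated to 35 nt, so inserts of 32-34 nt leave adapter fragments too
    short to recognize — the trimming artifact real fixed-length libraries
    show.  A single integer seed reproduces every output byte.
    """
    if tissue not in config.tissue_profiles:
        raise KeyError(f"tissue {tissue!r} not in config")
    profile = config.tissue_profiles[tissue]
    tissue_index = list(config.tissue_profiles).index(tissue)
    rng = np.random.default_rng([config.rng_seed, 1000 + tissue_index])
    params = AlignmentParams()

    weights = expression_weights(config, refs, tissue)
    offset_pairs = list(config.isomir_offsets)
    offset_probs = np.array([config.isomir_offsets[p] for p in offset_pairs], dtype=float)
    offset_probs /= offset_probs.sum()
    offsets = (offset_pairs, offset_probs)
    cond_offsets = _conditional_offsets(config.isomir_offsets)
    tier_names = list(config.tier_mix)
    tier_probs = np.array([config.tier_mix[t] for t in tier_names], dtype=float)

    n = profile.library_size
    origin_probs = [
        profile.mirna_fraction,
        profile.repeat_fraction,
        1.0 - profile.mirna_fraction - profile.repeat_fraction,
    ]
    origins = rng.choice(3, size=n, p=origin_probs)
    ref_choices = rng.choice(len(refs), size=n, p=weights)
    tier_choices = rng.choice(len(tier_names), size=n, p=tier_probs / tier_probs.sum())

    # background insert lengths: broad 15-31 plus a small 32-35 tail that
    # exercises the untrimmable-read regime
    bg_lengths = list(range(15, 32)) + [32, 33, 34, 35]
    bg_probs = np.array([0.9 / 17] * 17 + [0.025] * 4)
    bg_probs /= bg_probs.sum()

    adapter = config.adapter
    records: list[tuple[str, str, str]] = []
    truth_rows = []
    qual = "I" * RAW_LENGTH
    for i in range(n):
        origin = origins[i]
        if origin == 0:
            ref = refs[ref_choices[i]]
            tier = tier_names[tier_choices[i]]
            insert, o5, o3 = _build_mirna_insert(
                rng, ref, tier, offsets, cond_offsets, params
            )
            if config.substitution_rate > 0:
                for pos in range(len(insert)):
                    if rng.random() < config.substitution_rate:
                        insert = _mutate(rng, insert, pos)
            truth = {
                "origin": "mirna", "source_id": ref.id, "family": fru_family(ref.id),
                "intended_tier": tier, "offset_5p": o5, "offset_3p": o3,
            }
        elif origin == 1:
            length = int(rng.choice(PIRNA_LENGTHS, p=PIRNA_LENGTH_WEIGHTS))
            rid, rep_seq = repeats[rng.integers(0, len(repeats))]
            start = int(rng.integers(0, len(rep_seq) - length + 1))
            insert = rep_seq[start : start + length]
            if rng.random() < 0.5:
                insert = insert.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            truth = {
                "origin": "repeat", "source_id": rid, "family": "",
                "intended_tier": "", "offset_5p": pd.NA, "offset_3p": pd.NA,
            }
        else:
            length = int(rng.choice(bg_lengths, p=bg_probs))
            insert = _random_seq(rng, length)
            truth = {
                "origin": "background", "source_id": "", "family": "",
                "intended_tier": "", "offset_5p": pd.NA, "offset_3p": pd.NA,
            }
        raw = insert + adapter
        if len(raw) < RAW_LENGTH:
            raw += _random_seq(rng, RAW_LENGTH - len(raw))
        raw = raw[:RAW_LENGTH]
        read_id = f"{tissue}_r{i}"
        records.append((read_id, raw, qual))
        truth_rows.append(
            {"read_id": read_id, **truth, "insert_length": len(insert), "insert": insert}
        )
    truth_df = pd.DataFrame(truth_rows)
    return records, truth_df


@dataclass(slots=True)
class SimulatedDataset:
    config: SimulationConfig
    refs: list[MatureReference]
    repeats: list[tuple[str, str]]
    libraries: dict[str, tuple[list[tuple[str, str, str]], pd.DataFrame]]


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Generate the reference set and every configured tissue library.

    With ``out_dir`` set, writes ``reference.fa``, ``repeats.fa``, one
    FASTQ and one truth TSV per tissue, and a ``manifest.tsv``.
    """
    refs, repeats = make_reference(config)
    libraries = {
        tissue: simulate_library(config, tissue, refs, repeats)
        for tissue in config.tissue_profiles
    }
    dataset = SimulatedDataset(config=config, refs=refs, repeats=repeats, libraries=libraries)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "reference.fa", "w") as fh:
            for ref in refs:
                fh.write(f">{ref.id}\n{ref.sequence}\n")
        with open(out / "repeats.fa", "w") as fh:
            for rid, seq in repeats:
                fh.write(f">{rid}\n{seq}\n")
        manifest_rows = []
        for tissue, (records, truth) in libraries.items():
            fastq = out / f"{tissue}.fastq"
            write_fastq(records, fastq)
            truth.to_csv(out / f"{tissue}.truth.tsv", sep="\t", index=False)
            manifest_rows.append({"sample_path": str(fastq), "tissue": tissue})
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return dataset
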