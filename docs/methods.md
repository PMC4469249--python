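# Methods

## Scope and model

`srnakit` re-implements, as a reusable and tested pipeline, the analysis
design used to annotate and profile small RNAs from deep-sequenced fish
tissues: homology-based miRNA annotation of 18–25 nt reads against a
mature-miRNA reference set, expression profiling in reads per million,
isomiR terminal-variant taxonomy with seed-shift detection, ratio-based
differential expression, and characterization of the repeat-derived
26–31 nt population as putative piRNAs. The pipeline assumes single
(unreplicated) libraries per tissue, fixed-length raw reads carrying a 3'
sequencing adapter, and a reference of mature miRNA sequences only (no
precursors, no genome).

## Preprocessing

**Quality filter.** Reads with mean Phred quality below `min_mean_q`
(default 20) are removed; FASTA input passes through with a warning. The
threshold is a configuration value, not a constant of the method: any
fixed rule here is an assumption, so it is surfaced in the config.

**Adapter trimming.** The trimmer finds the leftmost position where
either the full adapter occurs (everything 3' of it is discarded) or a
3'-terminal fragment of the read is an adapter prefix of at least
`min_overlap` nt (default 4). Fragments of 1–3 nt are deliberately
retained — they cannot be distinguished from genuine small RNA sequence —
so fixed 35-nt raw reads can never trim to 32–34 nt. Matching is exact
(no mismatches), which makes that exclusion-zone property provable, and
the leftmost hit wins, the conservative choice for adapter dimers.
Trimming iterates to a fixpoint: a single pass is not idempotent in the
corner case where an insert itself ends in a ≥ 4-nt adapter prefix
(truncation exposes a new eligible suffix), and idempotence is the more
useful contract.

## Annotation cascade

Every collapsed 18–25 nt read receives exactly one label:

| tier | criterion |
|---|---|
| tier 1 | ungapped placement on some reference, 5' offset within ±2 nt, 3' offset within ±4 nt, all overlapping positions identical |
| tier 2 | first 10 nt identical to a reference; 5'-anchored contiguous identical run ≥ 16 nt |
| tier 3 | prefix identical, run < 16, Smith–Waterman score ≥ 70 (match +5, mismatch −4) |
| putative miRNA | prefix identical, neither run nor score criterion met |
| unannotated | no prefix-sharing reference and no tier-1 placement |

Design points:

* **Tier-1 extension nucleotides are unconstrained.** Nucleotides of the
  read that extend past either reference end cannot be validated without
  precursor or genome context, so they are accepted; this is stated in
  the output documentation rather than silently assumed.
* **Gap penalties.** Only match/mismatch scores are constants of the
  method. Gaps use the FASTA/Biopython affine convention — a gap of
  length k costs `gap_open + (k−1)·gap_extend`, defaults −12/−4 — and are
  configurable, including `use_gaps=False`. The test suite checks that
  tier-3 threshold decisions on short reads rarely change when gaps are
  disabled, since a single substitution, the dominant short-read event,
  never favors a gapped alignment at these penalties.
* **Tie-breaking** across references is deterministic: highest tier,
  then highest score (longest run for tier 2), then smallest
  |δ₅| + |δ₃|, then lexicographically smallest reference id.
* **Naming.** A read matched to any species' mature entry is reported
  under the `fru-`-prefixed family name of that entry (e.g.
  `dre-miR-1-3p` → `fru-miR-1-3p`), the convention for conserved miRNAs
  observed in a species annotated by homology.
* **Counting** is collapse-weighted: category proportions weight each
  unique sequence by its read multiplicity, so they are read-level
  percentages.
* A run of ≥ 16 identical nt alone scores 16 × 5 = 80 ≥ 70, so tier 2
  can never fall through to a sub-threshold tier 3; this inequality is
  asserted over whole simulated libraries.

## Profiling

Two RPM denominators are used on purpose and logged per tissue: miRNA
expression is normalized per million **18–25 nt** reads (the annotatable
window), size distributions per million **1–35 nt** reads. There are no
pseudocounts. Putative-miRNA expression is tabulated separately from the
tier 1–3 matrix rather than merged.

## IsomiRs and seed shifts

Terminal variation is defined on reference-relative end offsets, not raw
sequence comparison: the 5' offset is the available proxy for precursor
cleavage-site sliding when only mature references exist. Within each
(tissue, family) group the major isomiR is the highest-count variant
(ties: longer sequence, then lexicographic), elected **per tissue** —
the seed-shift report is a per-tissue table, so a global election would
suppress exactly the shifts it looks for. Variants are classified
relative to the major as identical / 3'-only / 5'-only / both; internal
substitutions with unchanged offsets are logged but excluded from the
terminal taxonomy, which is strictly about ends. The seed is positions
2–8 (1-based) of the 5' end; families whose per-tissue major seeds
disagree across at least two tissues are reported with per-tissue major
sequence, seed, and RPM.

## Differential expression

The statistic is the plain RPM ratio between two tissues; records pass
when fold > 1.5 and the **higher** tissue exceeds 1000 RPM. The
min-RPM filter applies to the higher tissue only: published worked
examples include pairs such as 2310 vs 30 RPM, which a both-tissue
reading would exclude. Folds are rounded half away from zero for
reporting. Zero-denominator records are flagged infinite and listed
separately, never ranked. With one library per condition there is no
replicate-based inference; every record carries a `putative` flag
instead of a significance column.

## Size classes and putative piRNAs

A read is repeat-derived if it (or its reverse complement) shares an
exact substring of ≥ `min_exact` nt (default 20) with a user-supplied
repeat FASTA. This is an explicit, reproducible stand-in for a live
homology search, not a reconstruction of one; at 20 nt the chance
collision probability per position is 4⁻²⁰. Putative piRNA = 26–31 nt
and repeat-derived. Composition assigns each 1–35 nt read one category
with precedence miRNA > putative miRNA > repeat-derived > unidentified;
the `other_annotated` category is kept in the schema but remains 0
because no rRNA/tRNA/mRNA annotation source is wired in. The
first-nucleotide composition of the putative-piRNA population is emitted
(1U bias is the classic piRNA diagnostic) but no threshold is applied to
it.

## Synthetic data generator

The generator emulates the statistical structure of the real libraries:

* fixed 35-nt raw reads = insert + 3' adapter + random fill, so the
  trimming exclusion zone is exercised on every library;
* somatic tissues: 75% miRNA-derived inserts (length mode 22 nt via the
  mature length distribution), 5% repeat-derived, 20% random background;
* gonadal tissues: 8% miRNA, 70% repeat-derived 26–31 nt inserts with
  mode 27 nt, 22% background;
* isomiR end offsets sampled from a configurable table with ~50% mass on
  canonical ends, ~49% on 3'-only variation and ~1% on any 5' shift,
  mirroring the observed dominance of 3' variation and rarity of 5'
  variation;
* tissue-specific expression planted through multipliers on named
  references; the planted high-abundance references are canonical
  22-mers, as dominant muscle miRNAs are, which keeps the somatic length
  mode at 22 nt;
* per-read truth records (origin, reference, offsets, intended tier,
  insert length) written alongside every library; a single integer seed
  reproduces every output byte.

MiRNA-origin reads are constructed to land in a chosen tier (mix
40/49/10/1% across tiers 1/2/3/putative): tier 2 via one substitution at
an anchored position ≥ 17, tier 3 via one substitution at positions
11–16, putative via an intact 10-nt prefix with a fully mismatching
templated tail. This makes tier ground truth exact by construction. The
putative-tail sampler additionally rejects candidates whose alignment
score reaches 70 — a calibration guard against rare chance alignments;
tier 1–3 truth is construction-guaranteed and independent of the
classifier. 3'-extension nucleotides are drawn uniformly at random,
since templated extension is unknowable without hairpin context.

**What the benchmark does not show.** Synthetic reads have uniform base
composition, no sequencing-error model beyond the optional
`substitution_rate`, no quality-score structure, no adapter mismatches,
and reference sets with pairwise-distinct 10-nt prefixes (real miRNA
families share prefixes and make tie-breaking matter more). Passing the
recovery tests demonstrates that the pipeline measures what the
generator planted under these idealized conditions; it does not validate
base-calling, real adapter chemistry, or homology search against full
databases.

## Problem sizes and numerical choices

The benchmark runs at 10⁵ reads per tissue across three tissues — large
enough that planted fold changes are measured to ~1% sampling error
while the whole suite stays interactive; unit and property tests use
4,000-read libraries. Study-scale quantities (10⁸ raw reads, full
miRBase-size references, per-tissue percentages of a specific animal)
require the original archived data and are out of scope; the synthetic
benchmark replaces them with ground-truth recovery at reduced scale.
Tolerances: tier composition within ±3 percentage points of truth,
planted folds within ±10% relative error, isomiR class fractions within
±2 points. Floating-point comparisons in tests use pytest's default
relative tolerance; RPM values are exact ratios scaled by 10⁶.

Degenerate inputs are defined throughout: empty libraries are errors for
distributions, empty reference sets annotate everything `unannotated`
with a warning, empty repeat sets match nothing with a warning,
zero-denominator folds are flagged infinite, and ties everywhere break
deterministically so reruns are byte-identical.
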