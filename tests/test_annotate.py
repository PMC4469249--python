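import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import sw_bruteforce, tier1_bruteforce
from srnakit.annotate import (
    PUTATIVE,
    TIER1,
    TIER2,
    TIER3,
    TIERS,
    UNANNOTATED,
    AlignmentParams,
    AnnotationResult,
    annotate_library,
    classify_read,
    fru_family,
    longest_run,
    prefix10_candidates,
    sw_score,
    tier1_match,
)
from srnakit.io_formats import MatureReference, SmallRNARead

MIR1 = "TGGAATGTAAAGAAGTATGTAT"  # dre-miR-1-3p in the small_refs fixture

short_dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


def biopython_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -4
    return aligner


class TestSwScore:
    def test_identical_16mers_score_80(self):
        seq = "ACGTACGTACGTACGT"
        assert sw_score(seq, seq) == 80

    def test_disjoint_alphabets_score_zero(self):
        assert sw_score("AAAAAA", "CCCCCC") == 0

    def test_fourteen_match_island_hits_threshold_exactly(self):
        island = "ACGTTGCAACGTTG"  # 14 nt
        embedded = "GGGG" + island + "GGGG"
        assert sw_score(embedded, island) == 70

    def test_score_is_symmetric(self):
        a, b = "ACGTACGTAAC", "ACGTTACGT"
        assert sw_score(a, b) == sw_score(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sw_score("", "ACGT")

    @given(a=short_dna, b=short_dna)
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_enumeration(self, a, b):
        assert sw_score(a, b) == sw_bruteforce(a, b)

    @given(a=short_dna, b=short_dna)
    @settings(max_examples=150, deadline=None)
    def test_matches_independent_library_aligner(self, a, b):
        assert sw_score(a, b) == int(biopython_aligner().score(a, b))

    @given(a=short_dna, b=short_dna, nt=st.sampled_from("ACGT"))
    @settings(max_examples=100, deadline=None)
    def test_appending_a_matching_nucleotide_never_decreases_scores(self, a, b, nt):
        assert sw_score(a + nt, b + nt) >= sw_score(a, b)
        assert longest_run(a + nt, b + nt) >= longest_run(a, b)


class TestTier1Match:
    def test_exact_copy_matches_with_zero_offsets(self):
        assert tier1_match(MIR1, MIR1) == (True, 0, 0)

    def test_3p_shortening_by_four_is_tolerated(self):
        assert tier1_match(MIR1[:-4], MIR1) == (True, 0, -4)

    def test_5p_shortening_by_three_is_rejected(self):
        ok, _, _ = tier1_match(MIR1[3:], MIR1)
        assert not ok

    def test_internal_substitution_fails_every_placement(self):
        read = MIR1[:10] + ("A" if MIR1[10] != "A" else "C") + MIR1[11:]
        ok, _, _ = tier1_match(read, MIR1)
        assert not ok

    def test_5p_extension_nucleotides_are_unconstrained(self):
        ok, o5, o3 = tier1_match("GG" + MIR1[: len(MIR1) - 2], MIR1)
        assert (ok, o5, o3) == (True, -2, -2)

    @given(data=st.data())
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_placement_enumeration(self, data):
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        nt = "ACGT"
        ref = "".join(nt[i] for i in rng.integers(0, 4, int(rng.integers(18, 26))))
        if rng.random() < 0.5:
            o5 = int(rng.integers(-2, 3))
            read = ref[o5:] if o5 > 0 else "".join(nt[i] for i in rng.integers(0, 4, -o5)) + ref
            read = (read + "".join(nt[i] for i in rng.integers(0, 4, 8)))[
                : int(rng.integers(18, 26))
            ]
        else:
            read = "".join(nt[i] for i in rng.integers(0, 4, int(rng.integers(18, 26))))
        assert tier1_match(read, ref) == tier1_bruteforce(read, ref)


class TestPrefixAndRun:
    def test_identical_prefix_is_a_candidate(self, small_refs):
        assert small_refs[0] in prefix10_candidates(MIR1, small_refs)

    def test_difference_at_position_10_excludes(self, small_refs):
        read = MIR1[:9] + ("C" if MIR1[9] != "C" else "G") + MIR1[10:]
        assert small_refs[0] not in prefix10_candidates(read, small_refs)

    def test_difference_at_position_11_still_candidate(self, small_refs):
        read = MIR1[:10] + ("C" if MIR1[10] != "C" else "G") + MIR1[11:]
        assert small_refs[0] in prefix10_candidates(read, small_refs)

    def test_short_read_has_no_candidates(self, small_refs):
        assert prefix10_candidates("ACGTACG", small_refs) == []

    @pytest.mark.parametrize(
        "mutations,expected",
        [((), 22), ((16,), 16), ((10, 11), 10)],
        ids=["identical", "sub_at_pos17", "subs_at_pos11_12"],
    )
    def test_longest_run_on_mutated_copies(self, mutations, expected):
        read = list(MIR1)
        for idx in mutations:
            read[idx] = "A" if MIR1[idx] != "A" else "C"
        assert longest_run("".join(read), MIR1) == expected


class TestClassifyRead:
    def test_exact_reference_copy_is_tier1(self, small_refs):
        res = classify_read(MIR1, small_refs)
        assert res.tier == TIER1
        assert res.matched_id == "dre-miR-1-3p"
        assert (res.offset_5p, res.offset_3p) == (0, 0)

    def test_shared_prefix_with_16nt_run_is_tier2(self, small_refs):
        read = MIR1[:16] + ("C" if MIR1[16] != "C" else "G") + MIR1[17:]
        res = classify_read(read, small_refs)
        assert res.tier == TIER2
        assert res.longest_run == 16

    def test_broken_run_with_high_alignment_score_is_tier3(self, small_refs):
        read = MIR1[:12] + ("C" if MIR1[12] != "C" else "G") + MIR1[13:]
        res = classify_read(read, small_refs)
        assert res.tier == TIER3
        assert res.longest_run < 16
        assert res.sw_score >= 70

    def test_prefix_only_read_is_putative(self, small_refs):
        # frozen worked example: run 12, local score 60 (checked against the
        # brute-force enumerator)
        read = "TGGAATGTAAAGCCTGCGTGCG"
        res = classify_read(read, small_refs)
        assert res.tier == PUTATIVE
        assert res.longest_run == 12
        assert res.sw_score == 60

    def test_unrelated_read_is_unannotated(self, small_refs):
        res = classify_read("CACACACACACACACACACACA", small_refs)
        assert res.tier == UNANNOTATED
        assert res.matched_id is None

    def test_out_of_window_read_is_a_contract_violation(self, small_refs):
        with pytest.raises(ValueError):
            classify_read("ACGTACGTACGTACGTACGTACGTACGT", small_refs)

    def test_matched_family_carries_fru_prefix(self, small_refs):
        res = classify_read(MIR1, small_refs)
        assert res.family == "fru-miR-1-3p"
        assert fru_family("dre-miR-206-3p") == "fru-miR-206-3p"

    @given(data=st.data())
    @settings(max_examples=150, deadline=None)
    def test_cascade_invariants_hold_for_random_reads(self, data, small_refs):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        nt = "ACGT"
        if rng.random() < 0.6:
            base = small_refs[int(rng.integers(0, len(small_refs)))].sequence
            read = list(base)
            for _ in range(int(rng.integers(0, 4))):
                idx = int(rng.integers(0, len(read)))
                read[idx] = nt[int(rng.integers(0, 4))]
            read = "".join(read)[: int(rng.integers(18, 26))]
        else:
            read = "".join(nt[i] for i in rng.integers(0, 4, int(rng.integers(18, 26))))
        if not 18 <= len(read) <= 25:
            return
        res = classify_read(read, small_refs)
        assert res.tier in TIERS
        if res.tier == TIER1:
            assert abs(res.offset_5p) <= 2 and abs(res.offset_3p) <= 4
            assert res.matched_id is not None
        elif res.tier == TIER2:
            assert res.longest_run >= 16
        elif res.tier == TIER3:
            assert res.longest_run < 16 and res.sw_score >= 70

    @given(data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_a_16nt_run_guarantees_alignment_score_80(self, data):
        # tier 2 can never be "rescued away" by tier 3: 16 matches alone
        # score 16 x 5 = 80 >= 70
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        nt = "ACGT"
        a = "".join(nt[i] for i in rng.integers(0, 4, 22))
        b = list("".join(nt[i] for i in rng.integers(0, 4, 22)))
        start = int(rng.integers(0, 7))
        b[start : start + 16] = a[start : start + 16]
        b = "".join(b)
        if longest_run(a, b) >= 16:
            assert sw_score(a, b) >= 80


class TestGapSensitivity:
    def test_threshold_decisions_rarely_change_with_gaps_disabled(self, dataset, processed):
        """Tier-3 calls hinge on score >= 70; with the default penalties a
        single substitution never favors a gap, so gapped and ungapped
        scoring should disagree on almost no threshold decisions."""
        gapless = AlignmentParams(use_gaps=False)
        ref_by_prefix = {r.sequence[:10]: r for r in dataset.refs}
        decisions = flips = 0
        for lib in processed.values():
            for res in lib.results:
                if res.sw_score is None:  # only tier-3/putative reads score
                    continue
                ref = ref_by_prefix[res.sequence[:10]]
                ungapped = sw_score(res.sequence, ref.sequence, gapless)
                decisions += 1
                flips += (ungapped >= 70) != (res.sw_score >= 70)
        assert decisions > 50
        assert flips / decisions <= 0.02


class TestAnnotateLibrary:
    def test_library_of_exact_copies_is_all_tier1(self, small_refs):
        reads = [SmallRNARead(r.sequence, count=3) for r in small_refs]
        results, counts = annotate_library(reads, small_refs)
        assert counts[TIER1] == 12
        assert sum(counts.values()) == 12
        assert all(r.tier == TIER1 for r in results)

    def test_empty_library_has_zero_counts(self, small_refs):
        results, counts = annotate_library([], small_refs)
        assert results == []
        assert all(v == 0 for v in counts.values())

    def test_empty_reference_set_leaves_all_unannotated(self, caplog):
        reads = [SmallRNARead(MIR1)]
        with caplog.at_level("WARNING", logger="srnakit.annotate"):
            results, counts = annotate_library(reads, [])
        assert counts[UNANNOTATED] == 1
        assert "empty reference" in caplog.text

    def test_tier_counts_sum_to_window_total(self, processed):
        for lib in processed.values():
            assert sum(lib.tier_counts.values()) == sum(r.count for r in lib.results)

    def test_indexed_and_linear_classification_agree(self, dataset, processed):
        lib = processed["fast_muscle"]
        rng = np.random.default_rng(0)
        sample = rng.choice(len(lib.results), size=min(60, len(lib.results)), replace=False)
        for i in sample:
            res = lib.results[i]
            plain = classify_read(
                SmallRNARead(res.sequence, count=res.count, tissue=res.tissue),
                dataset.refs,
            )
            assert (plain.tier, plain.matched_id) == (res.tier, res.matched_id)
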