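import pytest

from srnakit.annotate import TIER1, UNANNOTATED, AnnotationResult
from srnakit.isomir import (
    IDENTICAL,
    VAR_3P,
    VAR_5P,
    VAR_BOTH,
    IsomiRVariant,
    class_fractions,
    classify_variant,
    group_by_parent,
    major_isomir,
    seed_of,
    seed_shift_report,
)
from srnakit.published_tables import SEED_EXAMPLES


def result(seq, count, tissue, family, o5, o3, tier=TIER1):
    return AnnotationResult(
        sequence=seq, count=count, tissue=tissue, tier=tier,
        matched_id="x-" + family[4:] if family else None, family=family,
        offset_5p=o5, offset_3p=o3,
    )


class TestSeedOf:
    @pytest.mark.parametrize("sequence,seed", SEED_EXAMPLES)
    def test_published_major_isomir_seeds(self, sequence, seed):
        assert seed_of(sequence) == seed

    def test_sequence_shorter_than_eight_has_no_seed(self):
        with pytest.raises(ValueError):
            seed_of("ACGTACG")

    def test_seed_is_positions_two_to_eight(self):
        assert seed_of("ABCDEFGH") == "BCDEFGH"


class TestClassifyVariant:
    major = IsomiRVariant("G" * 22, 100, 0, 0)

    @pytest.mark.parametrize(
        "o5,o3,expected",
        [(0, 0, IDENTICAL), (0, -2, VAR_3P), (1, 0, VAR_5P), (-1, 1, VAR_BOTH)],
    )
    def test_offset_taxonomy(self, o5, o3, expected):
        assert classify_variant(IsomiRVariant("A" * 22, 1, o5, o3), self.major) == expected

    def test_internal_substitution_is_identical_at_termini(self):
        variant = IsomiRVariant("G" * 10 + "A" + "G" * 11, 1, 0, 0)
        assert classify_variant(variant, self.major) == IDENTICAL

    def test_major_against_itself_is_identical_in_every_group(self, processed):
        groups = group_by_parent(processed["fast_muscle"].results)
        for group in groups.values():
            assert classify_variant(group.major, group.major) == IDENTICAL


class TestMajorElection:
    def test_single_variant_is_its_own_major(self):
        v = IsomiRVariant("ACGTACGTACGT", 1, 0, 0)
        assert major_isomir([v]) is v

    def test_highest_count_wins(self):
        a = IsomiRVariant("A" * 22, 10, 0, 0)
        b = IsomiRVariant("C" * 22, 3, 0, -1)
        assert major_isomir([a, b]) is a

    def test_count_tie_goes_to_longer_then_lexicographic(self):
        short = IsomiRVariant("C" * 21, 5, 0, -1)
        long_a = IsomiRVariant("A" * 22, 5, 0, 0)
        long_c = IsomiRVariant("C" * 22, 5, 0, 0)
        assert major_isomir([short, long_c, long_a]) is long_a

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            major_isomir([])


class TestGrouping:
    def test_two_variants_of_one_family_share_a_group(self):
        results = [
            result("A" * 22, 10, "heart", "fru-miR-1-3p", 0, 0),
            result("A" * 21, 2, "heart", "fru-miR-1-3p", 0, -1),
        ]
        groups = group_by_parent(results)
        assert set(groups) == {("heart", "fru-miR-1-3p")}
        assert len(groups[("heart", "fru-miR-1-3p")].variants) == 2

    def test_empty_input_is_empty(self):
        assert group_by_parent([]) == {}

    def test_unannotated_reads_are_excluded(self):
        results = [result("A" * 22, 1, "heart", None, None, None, tier=UNANNOTATED)]
        assert group_by_parent(results) == {}

    def test_every_tier123_read_lands_in_exactly_one_group(self, processed):
        lib = processed["fast_muscle"]
        groups = group_by_parent(lib.results)
        grouped = sum(g.total for g in groups.values())
        expected = sum(
            r.count for r in lib.results
            if r.tier in ("miRNA_tier1", "miRNA_tier2", "miRNA_tier3")
        )
        assert grouped == expected

    def test_class_fractions_sum_to_one(self, processed):
        groups = group_by_parent(processed["heart"].results)
        fractions = class_fractions(groups)
        assert fractions.sum() == pytest.approx(1.0)


class TestSeedShiftReport:
    totals = {"heart": 1000, "brain": 1000}

    def test_identical_majors_everywhere_are_excluded(self):
        results = [
            result("GTAACGGAACCCATAATGCAGCT", 10, t, "fru-miR-462-5p", 0, 0)
            for t in ("heart", "brain")
        ]
        report = seed_shift_report(group_by_parent(results), self.totals)
        assert report.empty

    def test_5p_shifted_major_in_one_tissue_is_reported_with_two_seeds(self):
        canonical = "GTAACGGAACCCATAATGCAGCT"
        shifted = canonical[1:]  # 5' shortened by one -> new seed
        results = [
            result(canonical, 50, "heart", "fru-miR-462-5p", 0, 0),
            result(shifted, 40, "heart", "fru-miR-462-5p", 1, 0),
            result(shifted, 60, "brain", "fru-miR-462-5p", 1, 0),
            result(canonical, 10, "brain", "fru-miR-462-5p", 0, 0),
        ]
        report = seed_shift_report(group_by_parent(results), self.totals)
        assert set(report["tissue"]) == {"heart", "brain"}
        assert set(report["seed"]) == {"TAACGGA", "AACGGAA"}
        heart_row = report[report.tissue == "heart"].iloc[0]
        assert heart_row.major_sequence == canonical
        assert heart_row.rpm == pytest.approx(50_000)

    def test_one_tissue_input_gives_empty_report(self):
        results = [result("GTAACGGAACCCATAATGCAGCT", 10, "heart", "fru-miR-462-5p", 0, 0)]
        report = seed_shift_report(group_by_parent(results), {"heart": 100})
        assert report.empty

    def test_rows_ordered_by_family_then_tissue(self, processed):
        groups = group_by_parent([r for lib in processed.values() for r in lib.results])
        totals = {t: lib.total_18_25 for t, lib in processed.items()}
        report = seed_shift_report(groups, totals)
        keys = list(zip(report["family"], report["tissue"]))
        assert keys == sorted(keys)
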