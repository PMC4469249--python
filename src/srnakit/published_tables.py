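"""Worked-example values from the *Takifugu rubripes* tissue small RNA
survey (GEO accession GSE65404).

``FOLD_ROWS`` holds the published top differentially expressed miRNAs
between muscle tissues and between gonads: miRNA family, comparison
(higher tissue, lower tissue), RPM in the higher tissue, the published
integer fold, and RPM in the lower tissue.  ``consistent`` marks rows
whose published RPM pair rounds (half away from zero) to the published
fold; the remaining rows were evidently computed from unrounded RPM values
and cannot be reproduced from the printed pair.

``SEED_EXAMPLES`` holds published major-isomiR sequences with their seed
(positions 2-8) for miRNAs whose major isomiR shifts at the 5' end between
tissues.
"""

from __future__ import annotations

# (mirna_id, tissue_high, tissue_low, rpm_high, published_fold, rpm_low, consistent)
FOLD_ROWS: list[tuple[str, str, str, float, int, float, bool]] = [
    # fast muscle > heart
    ("fru-miR-206-3p", "fast_muscle", "heart", 94778, 434, 218, False),
    ("fru-miR-10b-5p", "fast_muscle", "heart", 2310, 77, 30, True),
    ("fru-miR-10d-5p", "fast_muscle", "heart", 1516, 60, 25, False),
    ("fru-miR-133b-3p", "fast_muscle", "heart", 16735, 17, 1003, True),
    ("fru-miR-133-3p", "fast_muscle", "heart", 58952, 15, 3951, True),
    # heart > fast muscle
    ("fru-miR-144-5p", "heart", "fast_muscle", 1012, 51, 20, True),
    ("fru-miR-499-5p", "heart", "fast_muscle", 28506, 41, 699, True),
    ("fru-miR-187-3p", "heart", "fast_muscle", 1483, 37, 40, True),
    ("fru-miR-499a-5p", "heart", "fast_muscle", 1179, 33, 36, True),
    ("fru-miR-140-3p", "heart", "fast_muscle", 10721, 17, 613, True),
    # slow muscle > heart
    ("fru-miR-196a-5p", "slow_muscle", "heart", 1035, 1305, 1, False),
    ("fru-miR-206-3p", "slow_muscle", "heart", 115467, 529, 218, False),
    ("fru-miR-194-5p", "slow_muscle", "heart", 1065, 93, 12, False),
    ("fru-miR-192-5p", "slow_muscle", "heart", 11732, 85, 138, True),
    ("fru-miR-10b-5p", "slow_muscle", "heart", 2329, 77, 30, False),
    # heart > slow muscle
    ("fru-miR-187-3p", "heart", "slow_muscle", 1483, 16, 92, True),
    ("fru-miR-30e-3p", "heart", "slow_muscle", 4473, 16, 280, True),
    ("fru-miR-140-3p", "heart", "slow_muscle", 10721, 10, 1108, True),
    ("fru-miR-218a-5p", "heart", "slow_muscle", 1380, 8, 168, True),
    ("fru-miR-140-5p", "heart", "slow_muscle", 4288, 6, 673, True),
    # fast muscle > slow muscle
    ("fru-miR-30e-3p", "fast_muscle", "slow_muscle", 1239, 4, 280, True),
    ("fru-miR-133a-3p", "fast_muscle", "slow_muscle", 48921, 3, 14148, True),
    ("fru-miR-133a-5p", "fast_muscle", "slow_muscle", 14675, 3, 5286, True),
    ("fru-miR-3571-5p", "fast_muscle", "slow_muscle", 3257, 3, 1176, True),
    ("fru-miR-133-5p", "fast_muscle", "slow_muscle", 2581, 2, 1089, True),
    # slow muscle > fast muscle
    ("fru-miR-126b-5p", "slow_muscle", "fast_muscle", 1350, 12, 111, True),
    ("fru-miR-194-5p", "slow_muscle", "fast_muscle", 1065, 21, 50, True),
    ("fru-miR-499-5p", "slow_muscle", "fast_muscle", 9193, 13, 699, True),
    ("fru-miR-30e-5p", "slow_muscle", "fast_muscle", 6361, 11, 591, True),
    ("fru-miR-30c-5p", "slow_muscle", "fast_muscle", 6669, 4, 1601, True),
    # ovaries > testes
    ("fru-miR-214-3p", "ovaries", "testes", 3055, 24, 125, True),
    ("fru-miR-143-3p", "ovaries", "testes", 6965, 24, 293, True),
    ("fru-miR-202-5p", "ovaries", "testes", 9054, 22, 409, True),
    ("fru-miR-24-3p", "ovaries", "testes", 4170, 20, 208, True),
    ("fru-miR-145b-5p", "ovaries", "testes", 5933, 20, 302, True),
    # testes > ovaries
    ("fru-miR-2478-3p", "testes", "ovaries", 2691, 2, 1133, True),
    ("fru-miR-2898-3p", "testes", "ovaries", 1503, 2, 753, True),
]

# (sequence, seed) pairs of published major isomiRs with 5' variation
SEED_EXAMPLES: list[tuple[str, str]] = [
    ("GTAACGGAACCCATAATGCAGCT", "TAACGGA"),   # fru-miR-462-5p, canonical major
    ("TAACGGAACCCATAATGCAGCT", "AACGGAA"),    # fru-miR-462-5p, 5'-shifted major
    ("GTACAGTACTATGATAACTGA", "TACAGTA"),     # fru-miR-101b-3p, canonical major
    ("TACAGTACTATGATAACTGA", "ACAGTAC"),      # fru-miR-101b-3p, 5'-shifted major
    ("TTGGTCCCCTTCAACCAGCCGT", "TGGTCCC"),    # fru-miR-133-3p, canonical major
    ("TTTGGTCCCCTTCAACCAGCC", "TTGGTCC"),     # fru-miR-133-3p, 5'-shifted major
]

# parent mature sequences planted verbatim into every synthetic reference
PLANTED_PARENTS: dict[str, str] = {
    "fru-miR-462-5p": "GTAACGGAACCCATAATGCAGCT",
    "fru-miR-101b-3p": "GTACAGTACTATGATAACTGA",
    "fru-miR-133-3p": "TTGGTCCCCTTCAACCAGCCG",
}


def consistent_fold_rows() -> list[tuple[str, str, str, float, int, float]]:
    """Rows whose printed RPM pair reproduces the printed integer fold."""
    return [(m, a, b, hi, f, lo) for (m, a, b, hi, f, lo, ok) in FOLD_ROWS if ok]
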