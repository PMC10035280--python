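"""Primer canonicalization, deduplication and IUPAC matching semantics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primercover.oracle import oracle_sites
from primercover.primers import (
    IUPAC_SETS,
    Direction,
    Primer,
    PrimerError,
    canonicalize_primer,
    dedup_primers,
    find_matches,
    iupac_set,
    reverse_complement,
)

IUPAC = "ACGTRYSWKMBDHVN"


class TestCanonicalize:
    def test_case_and_rna_normalization(self):
        p = canonicalize_primer("OP_F001", "F", "acgru")
        assert p.sequence == "ACGRT"
        assert p.direction is Direction.forward

    def test_inosine_maps_to_n(self):
        p = canonicalize_primer("KP_F020", "F", "CAGCIGCCGCGGTAA")
        assert p.sequence == "CAGCNGCCGCGGTAA"

    def test_invalid_letter_reports_position(self):
        with pytest.raises(PrimerError, match="position 4"):
            canonicalize_primer("OP_F002", "F", "ACGX")

    def test_empty_sequence_rejected(self):
        with pytest.raises(PrimerError):
            canonicalize_primer("OP_F003", "F", "")

    @pytest.mark.parametrize(
        "raw,expected",
        [("F", Direction.forward), ("reverse", Direction.reverse), ("UI", Direction.unidentified)],
    )
    def test_direction_aliases(self, raw, expected):
        assert canonicalize_primer("X", raw, "ACGT").direction is expected


class TestDedup:
    def test_two_identical_sequences_merge(self):
        primers = [
            canonicalize_primer("OP_F001", "F", "ACGTACGTAC"),
            canonicalize_primer("OP_F002", "F", "acgtacgtac"),
            canonicalize_primer("OP_F003", "F", "TTTTACGTAC"),
        ]
        distinct, dup_map = dedup_primers(primers)
        assert [p.primer_id for p in distinct] == ["OP_F001", "OP_F003"]
        assert dup_map == {"OP_F001": ["OP_F002"]}

    def test_all_distinct_is_identity(self):
        primers = [
            canonicalize_primer(f"OP_F{i:03d}", "F", "ACGTACGTAC"[:6] + "ACGT"[i] * 4)
            for i in range(4)
        ]
        distinct, dup_map = dedup_primers(primers)
        assert distinct == primers
        assert dup_map == {}


class TestIupacTables:
    @pytest.mark.parametrize(
        "letter,bases",
        [("A", {"A"}), ("Y", {"C", "T"}), ("B", {"C", "G", "T"}), ("N", set("ACGT"))],
    )
    def test_base_sets(self, letter, bases):
        assert iupac_set(letter) == bases

    def test_all_15_letters_have_distinct_sets(self):
        assert len({iupac_set(c) for c in IUPAC}) == 15

    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AYG", "CRT")])
    def test_reverse_complement_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet=IUPAC, min_size=1, max_size=30))
    def test_reverse_complement_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet=IUPAC, min_size=1, max_size=20))
    def test_complement_preserves_base_sets(self, seq):
        # the complement of each letter's set equals the set of the complemented letter
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = reverse_complement(seq)
        for original, complemented in zip(seq, reversed(rc)):
            assert {comp[b] for b in iupac_set(original)} == iupac_set(complemented)


def fp(seq: str, direction: str = "F") -> Primer:
    return canonicalize_primer("OP_T001", direction, seq)


class TestFindMatches:
    def test_overlapping_degenerate_sites(self):
        hits = find_matches(fp("AR"), "AAGTAG")
        assert [(m.start, m.end) for m in hits] == [(1, 2), (2, 3), (5, 6)]

    def test_gap_never_matches(self):
        assert find_matches(fp("ACGT"), "AC-GT") == []

    def test_ambiguous_database_base_never_matches(self):
        assert find_matches(fp("NNNN"), "ACNT") == []
        assert find_matches(fp("NNNN"), "ACGT") != []

    def test_reverse_primer_found_on_sense_strand(self):
        primer = canonicalize_primer("OP_R001", "R", "ACCGT")  # footprint ACGGT
        hits = find_matches(primer, "TTACGGTTT")
        assert [(m.start, m.end) for m in hits] == [(3, 7)]

    def test_leading_gaps_occupy_frame_positions(self):
        primer = fp("ACGT")
        base = find_matches(primer, "TTACGTTT")
        shifted = find_matches(primer, "-" * 10 + "TTACGTTT")
        assert [(m.start + 10, m.end + 10) for m in base] == [
            (m.start, m.end) for m in shifted
        ]

    def test_sorted_and_duplicate_free(self):
        hits = find_matches(fp("AA"), "AAAAAA")
        starts = [m.start for m in hits]
        assert starts == sorted(starts) and len(set(starts)) == len(starts)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.text(alphabet=IUPAC, min_size=2, max_size=12),
        st.text(alphabet="ACGTN-", min_size=10, max_size=500),
        st.sampled_from(["F", "R"]),
    )
    def test_engine_equals_bruteforce_expansion_oracle(self, primer_seq, sequence, direction):
        """The regex engine equals exhaustive expansion of the degenerate primer."""
        import math

        from hypothesis import assume

        assume(math.prod(len(IUPAC_SETS[c]) for c in primer_seq) <= 4096)
        primer = fp(primer_seq, direction)
        engine = [(m.start, m.end) for m in find_matches(primer, sequence)]
        assert engine == oracle_sites(primer, sequence)
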