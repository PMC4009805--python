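"""Overlap alignment: worked examples, independent oracles, invariants."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexitrim import (
    AlignmentAcceptance,
    ConfigError,
    ScoringScheme,
    accept,
    min_accepted_score,
    overlap_align,
)

DEFAULT = ScoringScheme(1, -1, -6)


def brute_force_score(read, tag, scoring=DEFAULT):
    """Exhaustive recursion over all alignments with free end gaps.

    Trailing gaps are free because the recursion returns 0 once either
    sequence is exhausted; leading gaps are free via the max over start
    offsets on one sequence.  Exponential — use only at tiny lengths.
    """
    ms, mms, g = scoring.match_score, scoring.mismatch_score, scoring.gap_score

    def rec(i, j):
        if i == len(tag) or j == len(read):
            return 0
        sub = rec(i + 1, j + 1) + (
            ms if (tag[i] == read[j] and tag[i] not in "N.") else mms
        )
        return max(sub, rec(i + 1, j) + g, rec(i, j + 1) + g)

    return max(
        max(rec(i0, 0) for i0 in range(len(tag) + 1)),
        max(rec(0, j0) for j0 in range(len(read) + 1)),
    )


def biopython_score(read, tag, scoring=DEFAULT):
    """Independent free-end-gap alignment via Bio.Align.PairwiseAligner."""
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match_score
    a.mismatch_score = scoring.mismatch_score
    a.open_gap_score = a.extend_gap_score = scoring.gap_score
    a.end_insertion_score = 0
    a.end_deletion_score = 0
    return a.score(read, tag)


class TestWorkedExamples:
    def test_exact_tag_inside_read(self):
        aln = overlap_align("ACGTACGT", "ACGT", DEFAULT)
        assert aln.score == 4
        assert aln.mismatches == 0
        assert aln.gap_columns == 0

    def test_identity_alignment(self):
        aln = overlap_align("GATTACA", "GATTACA", DEFAULT)
        assert aln.score == 7 * DEFAULT.match_score
        assert aln.mismatches == aln.gap_columns == 0
        assert (aln.read_start, aln.read_end) == (0, 7)

    def test_free_end_gaps_beat_forced_overlap(self):
        # no placement of TT on AAAA scores better than skipping entirely
        aln = overlap_align("AAAA", "TT", DEFAULT)
        assert aln.score == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            overlap_align("", "ACGT", DEFAULT)

    def test_uncalled_never_matches(self):
        aln = overlap_align("NNNN", "NNNN", DEFAULT)
        assert aln.matches == 0

    def test_score_decomposition(self):
        aln = overlap_align("ACGTTTACGT", "ACGACG", DEFAULT)
        assert aln.score == (
            DEFAULT.match_score * aln.matches
            + DEFAULT.mismatch_score * aln.mismatches
            + DEFAULT.gap_score * aln.gap_columns
        )


class TestOracles:
    def test_exhaustive_tiny_two_letter_alphabet(self):
        """DP equals brute-force enumeration for every pair up to length 4."""
        seqs = []
        for length in range(1, 5):
            for i in range(2**length):
                seqs.append(
                    "".join("AC"[(i >> k) & 1] for k in range(length))
                )
        for read in seqs:
            for tag in seqs:
                assert overlap_align(read, tag, DEFAULT).score == \
                    brute_force_score(read, tag), (read, tag)

    def test_random_pairs_against_biopython(self):
        rng = random.Random(42)
        for _ in range(500):
            read = "".join(
                rng.choice("ACGT") for _ in range(rng.randint(1, 12))
            )
            tag = "".join(
                rng.choice("ACGT") for _ in range(rng.randint(1, 12))
            )
            assert overlap_align(read, tag, DEFAULT).score == \
                biopython_score(read, tag), (read, tag)


@settings(deadline=None, max_examples=200)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=8),
    st.text(alphabet="ACGT", min_size=1, max_size=8),
)
def test_score_symmetry(a, b):
    assert overlap_align(a, b, DEFAULT).score == \
        overlap_align(b, a, DEFAULT).score


@settings(deadline=None, max_examples=100)
@given(
    st.text(alphabet="ACGT", min_size=2, max_size=10),
    st.text(alphabet="ACGT", min_size=1, max_size=4),
)
def test_appending_matching_char_never_decreases_score(read, ch):
    before = overlap_align(read, read, DEFAULT).score
    after = overlap_align(read + ch, read + ch, DEFAULT).score
    assert after >= before


@settings(deadline=None, max_examples=50)
@given(st.integers(min_value=0, max_value=2**32))
def test_huge_gap_cost_suppresses_gaps(seed):
    """At gap cost -100 the best alignment of a 22-nt tag has no gaps."""
    rng = random.Random(seed)
    harsh = ScoringScheme(1, -1, -100)
    tag = "".join(rng.choice("ACGT") for _ in range(22))
    read = "".join(rng.choice("ACGT") for _ in range(50))
    assert overlap_align(read, tag, harsh).gap_columns == 0


class TestThresholdMapping:
    """T buys an error budget proportional to overlap length."""

    def test_seven_mer_threshold_two_tolerates_one_error(self):
        acc = AlignmentAcceptance(min_overlap=7, threshold=2.0)
        assert min_accepted_score(7, acc, DEFAULT) == pytest.approx(4.2)
        # one mismatch over 7 columns scores 5 -> accepted
        aln = overlap_align("CCAAAGT" + "ACGT" * 5, "CCAATGT", DEFAULT)
        assert aln.mismatches == 1 and aln.score == 5
        assert accept(aln, acc, DEFAULT)

    def test_seven_mer_default_threshold_tolerates_none(self):
        acc = AlignmentAcceptance(min_overlap=7, threshold=1.0)
        assert min_accepted_score(7, acc, DEFAULT) == pytest.approx(5.6)
        aln = overlap_align("CCAAAGT" + "ACGT" * 5, "CCAATGT", DEFAULT)
        assert not accept(aln, acc, DEFAULT)

    def test_two_mismatches_rejected_at_threshold_two(self):
        acc = AlignmentAcceptance(min_overlap=7, threshold=2.0)
        aln = overlap_align("CCAAAGT" + "ACGT" * 5, "CCTATGT", DEFAULT)
        assert aln.mismatches == 2 and aln.score == 3
        assert not accept(aln, acc, DEFAULT)

    def test_threshold_zero_requires_perfect_overlap(self):
        acc = AlignmentAcceptance(min_overlap=1, threshold=0.0)
        assert min_accepted_score(9, acc, DEFAULT) == 9 * DEFAULT.match_score

    def test_short_overlap_rejected_regardless_of_score(self):
        acc = AlignmentAcceptance(min_overlap=7, threshold=2.0)
        aln = overlap_align("ACGTA", "ACGTA", DEFAULT)
        assert aln.score == 5
        assert not accept(aln, acc, DEFAULT)


def test_scoring_scheme_validation():
    with pytest.raises(ConfigError):
        ScoringScheme(match_score=1, mismatch_score=1)
    with pytest.raises(ConfigError):
        ScoringScheme(gap_score=0)
    with pytest.raises(ConfigError):
        AlignmentAcceptance(min_overlap=0)
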