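"""Trim-mode semantics: search regions, implied trims, best-tag choice."""

import random

import pytest

from flexitrim import (
    AlignmentAcceptance,
    ConfigError,
    ScoringScheme,
    SequenceRecord,
    Space,
    TagRole,
    TagSequence,
    TrimMode,
    apply_trim,
    find_best_tag,
    implied_trim,
    overlap_align,
    search_region,
)
from flexitrim.colorspace import decode, encode, tag_to_colorspace
from flexitrim.tagdetect import TagMatch

DEFAULT = ScoringScheme(1, -1, -6)

SL1 = "GGTTTAATTACCCAAGTTTGAG"
SL2 = "GGTTTTAACCCAGTTACTCAAG"


def _read(seq, quals=True):
    q = tuple([30] * len(seq)) if quals else None
    return SequenceRecord("r", seq, q)


class TestSearchRegion:
    @pytest.mark.parametrize(
        "mode,expected",
        [
            (TrimMode.ANY, (0, 36)),
            (TrimMode.LEFT, (0, 36)),
            (TrimMode.RIGHT, (0, 36)),
            (TrimMode.LEFT_TAIL, (0, 7)),
            (TrimMode.RIGHT_TAIL, (29, 36)),
        ],
    )
    def test_region_per_mode(self, mode, expected):
        read = _read("A" * 36)
        tag = TagSequence("t", "CCAAAGT")
        assert search_region(read, tag, mode) == expected

    def test_tag_longer_than_read_degenerates_to_whole_read(self):
        read = _read("ACGT")
        tag = TagSequence("t", "ACGTACGT")
        assert search_region(read, tag, TrimMode.LEFT_TAIL) == (0, 4)


class TestImpliedTrim:
    def _alignment(self, s, e):
        # minimal concrete alignment with the given read coordinates
        aln = overlap_align("ACGTACGTAC"[s:e] or "A", "ACGTACGTAC"[s:e] or "A")
        return type(aln)(
            score=aln.score, read_start=s, read_end=e,
            tag_start=0, tag_end=e - s, matches=e - s, mismatches=0,
            gap_columns=0, cigar=f"{e - s}=",
        )

    def test_any_mode_keeps_longer_side(self):
        assert implied_trim(self._alignment(2, 6), TrimMode.ANY, 10) == (6, 10)
        assert implied_trim(self._alignment(6, 9), TrimMode.ANY, 10) == (0, 6)

    def test_any_mode_tie_keeps_five_prime_side(self):
        # sides [0,3) and [7,10) are both length 3
        assert implied_trim(self._alignment(3, 7), TrimMode.ANY, 10) == (0, 3)

    def test_left_keeps_suffix(self):
        assert implied_trim(self._alignment(0, 4), TrimMode.LEFT, 10) == (4, 10)

    def test_right_keeps_prefix(self):
        assert implied_trim(self._alignment(4, 8), TrimMode.RIGHT, 10) == (0, 4)


class TestFindBestTag:
    def test_splice_leader_exact_prefix(self):
        insert = "ACGTACGTACGTACGTAC"
        read = _read(SL1 + insert)
        tags = [
            TagSequence("SL1", SL1, TagRole.BARCODE),
            TagSequence("SL2", SL2, TagRole.BARCODE),
        ]
        acc = AlignmentAcceptance(min_overlap=20, threshold=0.0)
        match = find_best_tag(read, tags, TrimMode.LEFT_TAIL, DEFAULT, acc)
        assert match is not None and match.tag.name == "SL1"
        assert match.retained_interval == (22, len(read.sequence))
        assert apply_trim(read, match).sequence == insert

    def test_tie_goes_to_first_listed_tag(self):
        read = _read("CCAAAGT" + "ACGT" * 6)
        tags = [
            TagSequence("first", "CCAAAGT"),
            TagSequence("second", "CCAAAGT"),
        ]
        acc = AlignmentAcceptance(min_overlap=7, threshold=0.0)
        match = find_best_tag(read, tags, TrimMode.LEFT_TAIL, DEFAULT, acc)
        assert match.tag.name == "first"

    def test_no_similarity_returns_none(self):
        read = _read("A" * 30)
        tags = [TagSequence("t", "CGCGCGC")]
        acc = AlignmentAcceptance(min_overlap=7, threshold=0.0)
        assert find_best_tag(read, tags, TrimMode.ANY, DEFAULT, acc) is None

    def test_empty_tag_list_rejected(self):
        with pytest.raises(ConfigError):
            find_best_tag(_read("ACGT"), [], TrimMode.ANY)

    def test_space_mismatch_rejected(self):
        tag = TagSequence("t", "0123", space=Space.COLOR)
        with pytest.raises(ConfigError):
            find_best_tag(_read("ACGTACGT"), [tag], TrimMode.ANY)


class TestApplyTrim:
    def test_slice_keeps_qualities_in_sync(self):
        read = SequenceRecord("r", "A" * 36, tuple(range(36)))
        match = TagMatch(
            TagSequence("t", "AAAAAAA"),
            overlap_align("A" * 7, "A" * 7),
            (7, 36),
        )
        out = apply_trim(read, match)
        assert len(out.sequence) == 29
        assert out.qualities == tuple(range(7, 36))

    def test_full_trim_gives_empty_read(self):
        read = _read("ACGTACG")
        match = TagMatch(
            TagSequence("t", "ACGTACG"),
            overlap_align("ACGTACG", "ACGTACG"),
            (0, 0),
        )
        assert len(apply_trim(read, match).sequence) == 0

    def test_color_left_trim_drops_junction_color(self):
        # letters: barcode ACGTA + insert GGTTCC; trimming the barcode
        # must drop its colors plus the junction color, and the decoded
        # remainder must equal the insert from its second base on
        letters = "ACGTA" + "GGTTCC"
        cs = encode(letters)
        read = SequenceRecord(
            "r", cs, tuple([30] * (len(cs) - 1)), Space.COLOR
        )
        tag_colors = tag_to_colorspace("ACGTA")
        tags = [TagSequence("bc", tag_colors, space=Space.COLOR)]
        acc = AlignmentAcceptance(min_overlap=4, threshold=0.0)
        match = find_best_tag(read, tags, TrimMode.LEFT_TAIL, DEFAULT, acc)
        assert match is not None
        out = apply_trim(read, match)
        assert not out.has_primer
        # remaining colors encode insert transitions G->G, G->T, T->T, T->C, C->C
        assert out.sequence == tag_to_colorspace("GGTTCC")
        assert decode("G" + out.sequence) == "GGTTCC"
        assert out.qualities is not None
        assert len(out.qualities) == len(out.sequence)


class TestTrimProperties:
    def test_random_triples_satisfy_mode_semantics(self):
        rng = random.Random(1234)
        modes = list(TrimMode)
        for _ in range(400):
            n = rng.randint(10, 60)
            m = rng.randint(3, min(9, n - 1))
            read_seq = "".join(rng.choice("ACGT") for _ in range(n))
            pos = rng.randint(0, n - m)
            tag_seq = read_seq[pos:pos + m]  # plant an exact copy
            mode = rng.choice(modes)
            read = _read(read_seq)
            tag = TagSequence("t", tag_seq)
            acc = AlignmentAcceptance(min_overlap=m, threshold=0.0)
            match = find_best_tag(read, [tag], mode, DEFAULT, acc)
            if match is None:
                continue
            s, e = match.alignment.read_start, match.alignment.read_end
            lo, hi = match.retained_interval
            assert 0 <= lo <= hi <= n
            assert hi <= s or lo >= e  # retained never overlaps the match
            out = apply_trim(read, match)
            assert len(out.sequence) <= n
            if mode is TrimMode.ANY:
                assert (hi - lo) == max(s, n - e)
            elif mode.is_left:
                assert (lo, hi) == (e, n)
                if mode is TrimMode.LEFT_TAIL:
                    # the distal n-m characters are untouched
                    assert out.sequence == read_seq[e:]
                    assert out.sequence.endswith(read_seq[m:])
            else:
                assert (lo, hi) == (0, s)
                if mode is TrimMode.RIGHT_TAIL:
                    # first n-m characters never modified
                    assert read_seq.startswith(out.sequence[: n - m])

    def test_adapter_removal_idempotent_on_clean_reads(self):
        rng = random.Random(99)
        adapter = "AGATCGGAAGAGC"
        acc = AlignmentAcceptance(min_overlap=len(adapter), threshold=0.0)
        tag = TagSequence("ad", adapter)
        for _ in range(50):
            insert = "".join(rng.choice("ACGT") for _ in range(30))
            read = _read(insert + adapter)
            match = find_best_tag(read, [tag], TrimMode.RIGHT, DEFAULT, acc)
            assert match is not None
            trimmed = apply_trim(read, match)
            again = find_best_tag(trimmed, [tag], TrimMode.RIGHT, DEFAULT, acc)
            assert again is None
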