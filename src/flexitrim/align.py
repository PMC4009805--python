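"""Semi-global (overlap) alignment of a tag against a read region.

The recurrences are those of global Needleman-Wunsch alignment with a
linear gap penalty, but gaps at either end of either sequence are free:
the first row and column of the dynamic-programming matrix are
initialised with zeros and the optimum is taken over the last row and
column.  This finds the best placement of a tag that may overhang either
end of the read, which is exactly the geometry of adapter fragments and
barcodes in short reads.

Acceptance of an alignment couples a minimum overlap length with a
similarity threshold T.  T maps to a tolerated error budget that scales
with the overlap: the minimum accepted score for an overlap of L columns
is ``L*match - T*(L/10)*(match - mismatch)``.  With the default scoring
(match 1, mismatch -1, gap -6) this makes T=2 tolerate exactly one
substitution over a 7-mer barcode and T=1 none, matching the behaviour
documented for TruSeq-style 7-mer demultiplexing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

#: Characters that never match anything, including themselves: the
#: uncalled base 'N' (letter space) and uncalled color '.' (color space).
_UNCALLED = frozenset("N.n")


@dataclass(frozen=True)
class ScoringScheme:
    """Match / mismatch / gap scores for overlap alignment.

    Defaults (1, -1, -6) keep gaps expensive relative to substitutions,
    appropriate for Illumina-like error profiles.
    """

    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -6

    def __post_init__(self) -> None:
        if self.match_score <= self.mismatch_score:
            raise ConfigError("match score must exceed mismatch score")
        if self.gap_score > self.mismatch_score:
            raise ConfigError("gap score must not exceed mismatch score")


@dataclass(frozen=True)
class AlignmentAcceptance:
    """Minimum overlap length plus similarity threshold T >= 0."""

    min_overlap: int = 1
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")
        if self.threshold < 0:
            raise ConfigError("threshold must be non-negative")


@dataclass(frozen=True)
class OverlapAlignment:
    """Best overlap alignment of a tag against a read region.

    Coordinates are 0-based half-open on each sequence; ``overlap_length``
    counts alignment columns between the overlap start and end (matches,
    mismatches and internal gap columns; free end gaps are excluded).
    ``cigar`` is a read-relative edit string: ``=`` match, ``X``
    mismatch, ``I`` read base absent from the tag, ``D`` tag base absent
    from the read.
    """

    score: int
    read_start: int
    read_end: int
    tag_start: int
    tag_end: int
    matches: int
    mismatches: int
    gap_columns: int
    cigar: str

    @property
    def overlap_length(self) -> int:
        return self.matches + self.mismatches + self.gap_columns


def _is_match(a: str, b: str) -> bool:
    return a == b and a not in _UNCALLED


def overlap_align(
    read_region: str, tag: str, scoring: ScoringScheme = ScoringScheme()
) -> OverlapAlignment:
    """Return the maximum-score overlap alignment of ``tag`` vs ``read_region``.

    Ties among equal-score optima in the last row/column are broken by
    scanning the last row left-to-right, then the last column
    top-to-bottom, and taking the first maximum; traceback prefers
    diagonal over tag-gap over read-gap moves.  Uncalled positions
    ('N'/'.') score as mismatches against everything.
    """
    n, m = len(read_region), len(tag)
    if n == 0 or m == 0:
        raise ConfigError("overlap_align requires non-empty sequences")
    ms, mms, gs = scoring.match_score, scoring.mismatch_score, scoring.gap_score

    # H[i][j]: best score of an alignment ending at tag[:i] / read[:j].
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        ti = tag[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (ms if _is_match(read_region[j - 1], ti) else mms)
            up = prev[j] + gs      # gap in read: consume tag
            left = row[j - 1] + gs  # gap in tag: consume read
            best = sub
            if up > best:
                best = up
            if left > best:
                best = left
            row[j] = best

    # locate the optimum: last row left-to-right, then last column top-down
    best_score = H[m][0]
    end_i, end_j = m, 0
    for j in range(n + 1):
        if H[m][j] > best_score:
            best_score, end_i, end_j = H[m][j], m, j
    for i in range(m + 1):
        if H[i][n] > best_score:
            best_score, end_i, end_j = H[i][n], i, n

    # traceback to the first row or column
    i, j = end_i, end_j
    matches = mismatches = gaps = 0
    ops: list[str] = []
    while i > 0 and j > 0:
        here = H[i][j]
        diag = H[i - 1][j - 1] + (
            ms if _is_match(read_region[j - 1], tag[i - 1]) else mms
        )
        if here == diag:
            if _is_match(read_region[j - 1], tag[i - 1]):
                matches += 1
                ops.append("=")
            else:
                mismatches += 1
                ops.append("X")
            i -= 1
            j -= 1
        elif here == H[i - 1][j] + gs:
            gaps += 1
            ops.append("D")
            i -= 1
        else:
            gaps += 1
            ops.append("I")
            j -= 1

    ops.reverse()
    cigar = _compress(ops)
    return OverlapAlignment(
        score=best_score,
        read_start=j,
        read_end=end_j,
        tag_start=i,
        tag_end=end_i,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        cigar=cigar,
    )


def _compress(ops: list[str]) -> str:
    out: list[str] = []
    run, count = "", 0
    for op in ops:
        if op == run:
            count += 1
        else:
            if run:
                out.append(f"{count}{run}")
            run, count = op, 1
    if run:
        out.append(f"{count}{run}")
    return "".join(out)


def min_accepted_score(
    overlap_length: int,
    acceptance: AlignmentAcceptance,
    scoring: ScoringScheme = ScoringScheme(),
) -> float:
    """Minimum alignment score accepted for an overlap of given length.

    ``L*match - T*(L/10)*(match - mismatch)``: the threshold T buys an
    error budget proportional to the overlap length.  T=0 accepts only
    perfect overlaps.
    """
    if overlap_length < 1:
        raise ConfigError("overlap_length must be >= 1")
    L, T = overlap_length, acceptance.threshold
    return L * scoring.match_score - T * (L / 10.0) * (
        scoring.match_score - scoring.mismatch_score
    )


def accept(
    alignment: OverlapAlignment,
    acceptance: AlignmentAcceptance,
    scoring: ScoringScheme = ScoringScheme(),
) -> bool:
    """True iff the alignment passes both the overlap and score gates."""
    L = alignment.overlap_length
    if L < acceptance.min_overlap or L < 1:
        return False
    return alignment.score >= min_accepted_score(L, acceptance, scoring)
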