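"""Tag (barcode/adapter) detection and the trim each detection implies.

Five trim modes control where a tag is looked for and which part of the
read is removed, named for the read end that is trimmed:

* ``ANY`` — tag anywhere; the longer non-matching side is retained.
* ``LEFT`` — tag in a read prefix; prefix through the match is removed.
* ``RIGHT`` — tag in a read suffix; suffix from the match is removed.
* ``LEFT_TAIL`` / ``RIGHT_TAIL`` — like LEFT/RIGHT, but only the first /
  last m positions of the read (m = tag length) are searched.

For LEFT and RIGHT the alignment itself searches the whole read and the
trim semantics remove everything from the match to the respective end;
only the TAIL modes restrict the dynamic-programming search region.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .align import (
    AlignmentAcceptance,
    OverlapAlignment,
    ScoringScheme,
    accept,
    overlap_align,
)
from .errors import ConfigError
from .seqio import SequenceRecord, Space


class TrimMode(Enum):
    ANY = "ANY"
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    LEFT_TAIL = "LEFT_TAIL"
    RIGHT_TAIL = "RIGHT_TAIL"

    @property
    def is_left(self) -> bool:
        return self in (TrimMode.LEFT, TrimMode.LEFT_TAIL)

    @property
    def is_right(self) -> bool:
        return self in (TrimMode.RIGHT, TrimMode.RIGHT_TAIL)


class TagRole(Enum):
    BARCODE = "barcode"
    ADAPTER = "adapter"


@dataclass(frozen=True)
class TagSequence:
    """A named barcode or adapter with the space it is matched in.

    For color-space runs the sequence is the color digit string (no
    primer base), as produced by :func:`flexitrim.colorspace.tag_to_colorspace`.
    """

    name: str
    sequence: str
    role: TagRole = TagRole.ADAPTER
    space: Space = Space.LETTER

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConfigError(f"tag {self.name!r} has an empty sequence")


@dataclass(frozen=True)
class TagMatch:
    """An accepted tag detection and the read interval that survives it.

    ``retained_interval`` is 0-based half-open over the read's scored
    positions (letters, or colors for color-space reads).
    """

    tag: TagSequence
    alignment: OverlapAlignment
    retained_interval: tuple[int, int]


def _matchable(read: SequenceRecord) -> str:
    """The read text alignments run against: letters, or colors sans primer."""
    return read.colors if read.space is Space.COLOR else read.sequence


def search_region(
    read: SequenceRecord, tag: TagSequence, mode: TrimMode
) -> tuple[int, int]:
    """Subinterval of the read's matchable positions searched for ``tag``.

    TAIL modes restrict to the first/last m positions; all other modes
    search the whole read.  If the tag is longer than the read the region
    degenerates to the whole read.
    """
    n, m = len(_matchable(read)), len(tag.sequence)
    if mode is TrimMode.LEFT_TAIL and m <= n:
        return (0, m)
    if mode is TrimMode.RIGHT_TAIL and m <= n:
        return (n - m, n)
    return (0, n)


def implied_trim(
    alignment: OverlapAlignment, mode: TrimMode, n: int
) -> tuple[int, int]:
    """Retained read interval implied by an accepted alignment.

    LEFT modes retain [match_end, n); RIGHT modes retain [0, match_start);
    ANY retains the longer of the two sides (the 5' side on equal length).
    """
    s, e = alignment.read_start, alignment.read_end
    if mode.is_left:
        return (e, n)
    if mode.is_right:
        return (0, s)
    left, right = (0, s), (e, n)
    return right if (n - e) > s else left


def find_best_tag(
    read: SequenceRecord,
    tags: list[TagSequence],
    mode: TrimMode,
    scoring: ScoringScheme = ScoringScheme(),
    acceptance: AlignmentAcceptance = AlignmentAcceptance(),
    collector: list[tuple[TagSequence, OverlapAlignment, bool]] | None = None,
) -> TagMatch | None:
    """Align every tag against its search region; return the best accepted one.

    Ties on score are broken by tag input order (earlier wins).  Returns
    ``None`` when no tag alignment passes acceptance.  When ``collector``
    is given, every attempted (tag, alignment, accepted) triple is
    appended to it — used for alignment logging.
    """
    if not tags:
        raise ConfigError("find_best_tag called with an empty tag list")
    text = _matchable(read)
    if not text:
        return None
    n = len(text)
    best: TagMatch | None = None
    for tag in tags:
        if tag.space is not read.space:
            raise ConfigError(
                f"tag {tag.name!r} is {tag.space.value}-space but read "
                f"{read.id!r} is {read.space.value}-space"
            )
        lo, hi = search_region(read, tag, mode)
        aln = overlap_align(text[lo:hi], tag.sequence, scoring)
        if lo:
            aln = OverlapAlignment(
                score=aln.score,
                read_start=aln.read_start + lo,
                read_end=aln.read_end + lo,
                tag_start=aln.tag_start,
                tag_end=aln.tag_end,
                matches=aln.matches,
                mismatches=aln.mismatches,
                gap_columns=aln.gap_columns,
                cigar=aln.cigar,
            )
        ok = accept(aln, acceptance, scoring)
        if collector is not None:
            collector.append((tag, aln, ok))
        if not ok:
            continue
        if best is None or aln.score > best.alignment.score:
            best = TagMatch(tag, aln, implied_trim(aln, mode, n))
    return best


def apply_trim(read: SequenceRecord, match: TagMatch) -> SequenceRecord:
    """Cut the read down to the match's retained interval.

    Qualities are sliced in sync.  For a color-space read whose 5' side
    is removed, the color at the cut junction encodes a transition from a
    removed base and is dropped too; the result carries no primer base.
    """
    lo, hi = match.retained_interval
    if read.space is Space.COLOR:
        colors = read.colors
        if lo > 0:
            lo = min(lo + 1, hi)  # junction color is undefined after the cut
            new_seq = colors[lo:hi]
        else:
            primer = read.sequence[0] if read.has_primer else ""
            new_seq = primer + colors[:hi]
        quals = read.qualities[lo:hi] if read.qualities is not None else None
        return SequenceRecord(read.id, new_seq, quals, Space.COLOR)
    quals = read.qualities[lo:hi] if read.qualities is not None else None
    return SequenceRecord(read.id, read.sequence[lo:hi], quals, Space.LETTER)
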