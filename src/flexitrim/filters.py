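"""Read filtering and quality clipping.

These are the per-read gates and cuts that run around tag detection:
an uncalled-base filter, fixed-length end trims, Phred-score clipping
from the 3' end, truncation to a target length, and the final minimum-
length gate.  Each operates on letters in letter space and on colors in
color space (uncalled means 'N' or '.', respectively), and each is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError
from .seqio import SequenceRecord, Space


@dataclass(frozen=True)
class FilterConfig:
    """Filter settings with their conventional defaults.

    By default no uncalled bases are allowed, fixed pre-trims and quality
    clipping are disabled, and reads shorter than 18 positions after all
    removal steps are dropped (shorter reads rarely map unambiguously).
    """

    max_uncalled: int = 0
    pre_trim_left: int = 0
    pre_trim_right: int = 0
    pre_trim_phred: int | None = None
    post_trim_length: int | None = None
    min_readlength: int = 18

    def __post_init__(self) -> None:
        if min(self.max_uncalled, self.pre_trim_left, self.pre_trim_right) < 0:
            raise ConfigError("filter counts must be non-negative")


def _scored_text(read: SequenceRecord) -> str:
    return read.colors if read.space is Space.COLOR else read.sequence


def _rebuild(read: SequenceRecord, lo: int, hi: int) -> SequenceRecord:
    """Slice a read to scored positions [lo, hi), qualities in sync."""
    text = _scored_text(read)
    lo, hi = max(lo, 0), min(hi, len(text))
    if hi < lo:
        hi = lo
    quals = read.qualities[lo:hi] if read.qualities is not None else None
    if read.space is Space.COLOR:
        primer = read.sequence[0] if (read.has_primer and lo == 0) else ""
        return SequenceRecord(read.id, primer + text[lo:hi], quals, Space.COLOR)
    return SequenceRecord(read.id, text[lo:hi], quals, Space.LETTER)


def count_uncalled(read: SequenceRecord) -> int:
    text = _scored_text(read)
    return text.count("N") + text.count(".") if read.space is Space.COLOR \
        else text.count("N")


def filter_uncalled(read: SequenceRecord, max_uncalled: int = 0) -> bool:
    """True (keep) iff the number of uncalled positions is within budget."""
    return count_uncalled(read) <= max_uncalled


def pre_trim_fixed(
    read: SequenceRecord, left: int = 0, right: int = 0
) -> SequenceRecord:
    """Remove exactly ``left`` 5' and ``right`` 3' scored positions.

    If ``left + right`` covers the read the result is empty (the length
    gate removes it downstream).
    """
    n = len(_scored_text(read))
    return _rebuild(read, left, n - right)


def pre_trim_phred(read: SequenceRecord, cutoff: int) -> SequenceRecord:
    """Clip low-quality positions from the 3' end.

    Scanning from the 3' end, positions with quality < cutoff are removed
    up to (not including) the first position with quality >= cutoff;
    everything 5' of that position is untouched.
    """
    if read.qualities is None:
        raise ConfigError(
            f"quality clipping requested but read {read.id!r} has no qualities"
        )
    hi = len(read.qualities)
    while hi > 0 and read.qualities[hi - 1] < cutoff:
        hi -= 1
    return _rebuild(read, 0, hi)


def post_trim_length(read: SequenceRecord, target_len: int) -> SequenceRecord:
    """Truncate the 3' end so at most ``target_len`` positions remain."""
    if len(_scored_text(read)) <= target_len:
        return read
    return _rebuild(read, 0, target_len)


def length_gate(read: SequenceRecord, min_readlength: int = 18) -> bool:
    """True (pass) iff the read keeps at least ``min_readlength`` positions."""
    return len(_scored_text(read)) >= min_readlength
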