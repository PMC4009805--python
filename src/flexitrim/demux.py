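"""Demultiplexing: assign reads to sample barcodes and route the output.

Barcodes either reside within the sequencing reads themselves (matched
and, unless ``keep_barcode`` is set, trimmed away) or arrive as a
separate barcode-read file, one barcode read per sequencing read (the
TruSeq "1/2 + 1" layout); in the separate case the sequencing read is
never touched by barcode matching.  Reads whose best barcode alignment
fails acceptance go to the UNASSIGNED stream, which is always
materialised.  Ties between equally scoring barcodes go to the one
listed first.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .align import AlignmentAcceptance, ScoringScheme
from .errors import ConfigError
from .seqio import SequenceRecord
from .tagdetect import TagMatch, TagSequence, TrimMode, apply_trim, find_best_tag

UNASSIGNED = "unassigned"


class BarcodeSource(Enum):
    WITHIN_READS = "within_reads"
    SEPARATE_READS = "separate_reads"


@dataclass(frozen=True)
class BarcodeSet:
    """An ordered barcode collection plus where to look for it."""

    barcodes: tuple[TagSequence, ...]
    source: BarcodeSource = BarcodeSource.WITHIN_READS
    keep_barcode: bool = False

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ConfigError("demultiplexing requires at least one barcode")
        names = [b.name for b in self.barcodes]
        if len(set(names)) != len(names):
            raise ConfigError("barcode names must be unique")


@dataclass(frozen=True)
class DemuxResult:
    """Outcome of barcode assignment for one read (or pair)."""

    barcode_name: str
    reads: tuple[SequenceRecord, ...]
    match: TagMatch | None = None


def assign_barcode(
    record: SequenceRecord,
    barcode_set: BarcodeSet,
    mode: TrimMode = TrimMode.ANY,
    scoring: ScoringScheme = ScoringScheme(),
    acceptance: AlignmentAcceptance | None = None,
    collector: list | None = None,
) -> tuple[str, TagMatch | None]:
    """Match ``record`` against the barcode set.

    ``record`` is the sequencing read for WITHIN_READS sources and the
    separate barcode read for SEPARATE_READS sources.  Returns the
    assigned barcode name (or UNASSIGNED) and the accepted match, if any.
    When ``acceptance`` is None the overlap requirement defaults to the
    full barcode length (barcodes are matched end to end, with the
    threshold supplying the error budget).
    """
    if acceptance is None:
        acceptance = full_length_acceptance(barcode_set)
    match = find_best_tag(
        record, list(barcode_set.barcodes), mode, scoring, acceptance,
        collector=collector,
    )
    if match is None:
        return UNASSIGNED, None
    return match.tag.name, match


def full_length_acceptance(
    barcode_set: BarcodeSet, threshold: float = 1.0
) -> AlignmentAcceptance:
    """Default barcode acceptance: overlap at least the shortest barcode."""
    return AlignmentAcceptance(
        min_overlap=min(len(b.sequence) for b in barcode_set.barcodes),
        threshold=threshold,
    )


def demultiplex_read(
    read: SequenceRecord,
    barcode_set: BarcodeSet,
    mode: TrimMode = TrimMode.ANY,
    scoring: ScoringScheme = ScoringScheme(),
    acceptance: AlignmentAcceptance | None = None,
    barcode_read: SequenceRecord | None = None,
    collector: list | None = None,
) -> DemuxResult:
    """Assign and, for within-read barcodes, trim one sequencing read."""
    if barcode_set.source is BarcodeSource.SEPARATE_READS:
        if barcode_read is None:
            raise ConfigError(
                "separate barcode reads configured but none supplied for "
                f"read {read.id!r}"
            )
        name, match = assign_barcode(
            barcode_read, barcode_set, mode, scoring, acceptance, collector
        )
        return DemuxResult(name, (read,), match)
    name, match = assign_barcode(
        read, barcode_set, mode, scoring, acceptance, collector
    )
    if match is not None and not barcode_set.keep_barcode:
        return DemuxResult(name, (apply_trim(read, match),), match)
    return DemuxResult(name, (read,), match)


class Router:
    """Append demux results to per-barcode sinks, conserving every read.

    ``sinks`` maps barcode name (plus UNASSIGNED) to a writer object with
    a ``write(record)`` method — a :class:`flexitrim.seqio.RecordWriter`
    or any list-like collector.  Paired routing uses ``(sink_1, sink_2)``
    tuples.
    """

    def __init__(self, sinks: dict[str, object]):
        self.sinks = sinks
        self.counts: dict[str, int] = {name: 0 for name in sinks}

    def route(self, result: DemuxResult) -> None:
        sink = self.sinks[result.barcode_name]
        if len(result.reads) == 1:
            self._write(sink, result.reads[0])
        else:
            for mate_sink, record in zip(sink, result.reads):
                self._write(mate_sink, record)
        self.counts[result.barcode_name] += 1

    @staticmethod
    def _write(sink, record: SequenceRecord) -> None:
        if hasattr(sink, "write"):
            sink.write(record)
        else:
            sink.append(record)
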