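"""End-to-end read processing: filters, demultiplexing, adapter removal.

One call runs the full per-read chain, in this fixed order:

1. uncalled-base filter (failing reads skip all tag processing)
2. fixed 5'/3' pre-trim
3. quality clipping from the 3' end
4. barcode assignment (and trim, for within-read barcodes)
5. adapter detection and trim
6. truncation to a target length
7. minimum-length gate
8. routing to the per-barcode / unassigned / short output streams

Paired-end reads move through the chain together: both mates are
processed with the same configuration and a pair is dropped from the
paired outputs as soon as either mate fails the length gate, so the
ordered id lists of the ``_1`` and ``_2`` output files are always
identical.  With ``single_reads`` the surviving mate of a broken pair is
diverted to a ``_single`` file instead of being discarded.

Worker parallelism is chunk-based with an ordered merge, so output
content and order are identical for any thread count.
"""

from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass, field
from enum import Enum
from itertools import islice
from pathlib import Path
from typing import IO, Iterator

from .align import AlignmentAcceptance, ScoringScheme
from .demux import (
    UNASSIGNED,
    BarcodeSet,
    BarcodeSource,
    demultiplex_read,
)
from .errors import ConfigError
from .filters import (
    FilterConfig,
    filter_uncalled,
    length_gate,
    post_trim_length,
    pre_trim_fixed,
    pre_trim_phred,
)
from .seqio import (
    Container,
    ReadFormat,
    RecordWriter,
    SequenceRecord,
    read_pairs,
    read_records,
)
from .tagdetect import TagSequence, TrimMode, apply_trim, find_best_tag

_CHUNK = 2048


class LogLevel(Enum):
    NONE = "NONE"
    ALL = "ALL"
    TAB = "TAB"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one processing run needs.

    ``barcode_acceptance=None`` means full-length barcode overlap with
    threshold 1; adapter defaults allow short 3' fragments (overlap >= 3).
    Neither barcode nor adapter processing is mandatory.
    """

    fmt: ReadFormat
    reads: str | Path
    reads2: str | Path | None = None
    barcode_reads: str | Path | None = None
    qual_file: str | Path | None = None
    target: str = "flexitrim_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    barcodes: BarcodeSet | None = None
    barcode_mode: TrimMode = TrimMode.ANY
    barcode_scoring: ScoringScheme = field(default_factory=ScoringScheme)
    barcode_acceptance: AlignmentAcceptance | None = None
    adapters: tuple[TagSequence, ...] = ()
    adapter_mode: TrimMode = TrimMode.RIGHT
    adapter_scoring: ScoringScheme = field(default_factory=ScoringScheme)
    adapter_acceptance: AlignmentAcceptance = field(
        default_factory=lambda: AlignmentAcceptance(min_overlap=3, threshold=1.0)
    )
    threads: int = 1
    write_short: bool = False
    single_reads: bool = False
    log_level: LogLevel = LogLevel.NONE

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ConfigError("threads must be >= 1")
        if self.barcode_reads is not None and self.barcodes is None:
            raise ConfigError("--barcode-reads given without --barcodes")
        if (
            self.barcodes is not None
            and self.barcodes.source is BarcodeSource.SEPARATE_READS
            and self.barcode_reads is None
        ):
            raise ConfigError(
                "barcode set expects separate barcode reads but no file given"
            )


@dataclass
class RunStats:
    """Per-run counters; conservation holds by construction:
    ``reads_in == sum(written.values()) + sum(discarded.values())``."""

    reads_in: int = 0
    bases_in: int = 0
    bases_out: int = 0
    written: dict[str, int] = field(default_factory=dict)
    discarded: dict[str, int] = field(default_factory=dict)
    per_barcode: dict[str, int] = field(default_factory=dict)

    def _bump(self, table: dict[str, int], key: str, by: int = 1) -> None:
        table[key] = table.get(key, 0) + by

    def as_lines(self) -> list[str]:
        lines = [
            f"reads_in: {self.reads_in}",
            f"bases_in: {self.bases_in}",
            f"bases_out: {self.bases_out}",
        ]
        for key in sorted(self.written):
            lines.append(f"written[{key}]: {self.written[key]}")
        for key in sorted(self.discarded):
            lines.append(f"discarded[{key}]: {self.discarded[key]}")
        if self.per_barcode:
            lines.append("barcode\treads")
            for name in sorted(self.per_barcode):
                lines.append(f"{name}\t{self.per_barcode[name]}")
        return lines


@dataclass(frozen=True)
class ReadOutcome:
    """What happened to one read: where it goes and what remains of it."""

    record: SequenceRecord
    barcode_name: str | None  # None when demultiplexing is off
    passed_gate: bool
    discard_reason: str | None  # "uncalled" | "too_short" | None
    input_length: int = 0  # scored positions before any trimming
    log_lines: tuple[str, ...] = ()


def process_read(
    read: SequenceRecord,
    config: PipelineConfig,
    barcode_read: SequenceRecord | None = None,
    skip_barcode: bool = False,
) -> ReadOutcome:
    """Run one read through filter, demux and adapter stages (no I/O).

    ``skip_barcode`` is used for mate 2 of a pair, whose barcode is
    decided by mate 1 (or by the separate barcode read).
    """
    f = config.filters
    n_in = read.n_scored
    collector: list | None = [] if config.log_level is not LogLevel.NONE else None

    if not filter_uncalled(read, f.max_uncalled):
        return ReadOutcome(read, None, False, "uncalled", n_in)

    if f.pre_trim_left or f.pre_trim_right:
        read = pre_trim_fixed(read, f.pre_trim_left, f.pre_trim_right)
    if f.pre_trim_phred is not None:
        read = pre_trim_phred(read, f.pre_trim_phred)

    barcode_name: str | None = None
    if config.barcodes is not None and not skip_barcode:
        result = demultiplex_read(
            read,
            config.barcodes,
            config.barcode_mode,
            config.barcode_scoring,
            config.barcode_acceptance,
            barcode_read=barcode_read,
            collector=collector,
        )
        barcode_name = result.barcode_name
        read = result.reads[0]

    if config.adapters and len(read):
        match = find_best_tag(
            read,
            list(config.adapters),
            config.adapter_mode,
            config.adapter_scoring,
            config.adapter_acceptance,
            collector=collector,
        )
        if match is not None:
            read = apply_trim(read, match)

    if f.post_trim_length is not None:
        read = post_trim_length(read, f.post_trim_length)

    passed = length_gate(read, f.min_readlength)
    log_lines = tuple(
        _format_log(read.id, tag, aln, ok, config.log_level)
        for tag, aln, ok in (collector or [])
    )
    return ReadOutcome(
        read, barcode_name, passed, None if passed else "too_short",
        n_in, log_lines,
    )


def _format_log(read_id, tag, aln, accepted, level: LogLevel) -> str:
    if level is LogLevel.TAB:
        return (
            f"{read_id}\t{tag.name}\t{aln.score}\t{aln.read_start}\t"
            f"{aln.read_end}\t{aln.cigar}\t{int(accepted)}"
        )
    return (
        f"read: {read_id}\n  tag: {tag.name}\n  score: {aln.score}\n"
        f"  read_interval: [{aln.read_start},{aln.read_end})\n"
        f"  tag_interval: [{aln.tag_start},{aln.tag_end})\n"
        f"  edits: {aln.cigar}\n  accepted: {accepted}\n"
    )


@dataclass(frozen=True)
class PairOutcome:
    mate1: ReadOutcome
    mate2: ReadOutcome
    barcode_name: str | None

    @property
    def both_pass(self) -> bool:
        return self.mate1.passed_gate and self.mate2.passed_gate


def process_pair(
    pair: tuple[SequenceRecord, SequenceRecord],
    config: PipelineConfig,
    barcode_read: SequenceRecord | None = None,
) -> PairOutcome:
    """Process both mates; the barcode is decided on mate 1 (or the
    separate barcode read) and shared by the pair."""
    out1 = process_read(pair[0], config, barcode_read=barcode_read)
    out2 = process_read(pair[1], config, skip_barcode=True)
    return PairOutcome(out1, out2, out1.barcode_name)


# ---------------------------------------------------------------------------
# run orchestration


class _LazyWriter:
    """Opens its output file lazily, or eagerly for always-materialised
    sinks (the per-barcode and unassigned streams must exist even when
    empty)."""

    def __init__(self, path: Path, fmt: ReadFormat, write_qual: bool,
                 eager: bool = False):
        self._path, self._fmt, self._wq = path, fmt, write_qual
        self._writer: RecordWriter | None = None
        self.count = 0
        if eager:
            self._writer = RecordWriter(path, fmt, write_qual)

    def write(self, record: SequenceRecord) -> None:
        if self._writer is None:
            self._writer = RecordWriter(self._path, self._fmt, self._wq)
        self._writer.write(record)
        self.count += 1

    def close(self) -> None:
        if self._writer is not None:
            self._writer.close()


class _Sinks:
    """All output files of a run, keyed by sink name."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        fmt = config.fmt
        self._write_qual = (
            fmt.container is Container.CSFASTA and config.qual_file is not None
        )
        self.paired = config.reads2 is not None
        names = [""]
        if config.barcodes is not None:
            names = [b.name for b in config.barcodes.barcodes] + [UNASSIGNED]
        self.names = names
        self.writers: dict[str, tuple[_LazyWriter, ...]] = {}
        for name in names:
            self.writers[name] = tuple(
                self._make(name, mate, eager=True) for mate in
                ((1, 2) if self.paired else (0,))
            )
        self.short = (
            tuple(
                self._make("short", mate)
                for mate in ((1, 2) if self.paired else (0,))
            )
            if config.write_short
            else None
        )
        self.single = (
            self._make("single", 0) if config.single_reads else None
        )
        self.uncalled = self._make("uncalled", 0)

    def _make(self, name: str, mate: int, eager: bool = False) -> _LazyWriter:
        parts = [self.config.target]
        if name:
            parts.append(name)
        if mate:
            parts.append(str(mate))
        path = Path("_".join(parts) + "." + self.config.fmt.extension)
        return _LazyWriter(path, self.config.fmt, self._write_qual, eager)

    def close(self) -> None:
        for writers in self.writers.values():
            for w in writers:
                w.close()
        for group in (self.short or ()):
            group.close()
        if self.single is not None:
            self.single.close()
        self.uncalled.close()


def _chunks(iterator: Iterator, size: int) -> Iterator[list]:
    while True:
        block = list(islice(iterator, size))
        if not block:
            return
        yield block


def run(config: PipelineConfig) -> RunStats:
    """Execute a full processing run; returns the collected statistics.

    Writes per-sink sequence files named ``<target>[_<barcode>][_mate].<ext>``,
    a ``<target>.log`` statistics file and, when alignment logging is
    on, ``<target>_align.log``.  Output is deterministic for a fixed
    config and input regardless of ``threads``.
    """
    stats = RunStats()
    sinks = _Sinks(config)
    demuxing = config.barcodes is not None
    log_handle: IO[str] | None = None
    if config.log_level is not LogLevel.NONE:
        log_handle = open(f"{config.target}_align.log", "w")
        if config.log_level is LogLevel.TAB:
            log_handle.write(
                "read_id\ttag\tscore\tread_start\tread_end\tedits\taccepted\n"
            )

    barcode_iter: Iterator[SequenceRecord] | None = None
    if config.barcode_reads is not None:
        barcode_iter = read_records(config.barcode_reads, config.fmt)

    def worker_single(block):
        out = []
        for read, bread in block:
            out.append(process_read(read, config, barcode_read=bread))
        return out

    def worker_paired(block):
        return [process_pair(pair, config, barcode_read=bread)
                for pair, bread in block]

    try:
        if config.reads2 is None:
            source = read_records(config.reads, config.fmt, config.qual_file)
            items = _attach_barcode_reads(source, barcode_iter, config)
            for outcome in _map_ordered(worker_single, items, config.threads):
                _emit_single(outcome, sinks, stats, demuxing, log_handle)
        else:
            source = read_pairs(config.reads, config.reads2, config.fmt)
            items = _attach_barcode_reads(source, barcode_iter, config)
            for outcome in _map_ordered(worker_paired, items, config.threads):
                _emit_pair(outcome, sinks, stats, demuxing, log_handle)
    finally:
        sinks.close()
        if log_handle is not None:
            log_handle.close()

    for name, writers in sinks.writers.items():
        stats.written[name or "out"] = sum(w.count for w in writers)
        if demuxing and name != UNASSIGNED:
            stats.per_barcode[name] = writers[0].count
    with open(f"{config.target}.log", "w") as handle:
        handle.write("\n".join(stats.as_lines()) + "\n")
    return stats


def _attach_barcode_reads(source, barcode_iter, config):
    if barcode_iter is None:
        return ((item, None) for item in source)

    def zipped():
        for item in source:
            bread = next(barcode_iter, None)
            if bread is None:
                raise ConfigError(
                    "fewer barcode reads than sequencing reads"
                )
            yield item, bread

    return zipped()


def _map_ordered(worker, items, threads: int):
    """Apply ``worker`` to chunks of ``items``, preserving input order.

    Submission is bounded so memory stays flat: at most ``threads + 2``
    chunks are in flight, and results are yielded strictly in input order.
    """
    chunk_iter = _chunks(iter(items), _CHUNK)
    if threads == 1:
        for block in chunk_iter:
            yield from worker(block)
        return
    from collections import deque

    with concurrent.futures.ThreadPoolExecutor(max_workers=threads) as pool:
        pending: deque = deque()
        for block in chunk_iter:
            pending.append(pool.submit(worker, block))
            if len(pending) > threads + 2:
                yield from pending.popleft().result()
        while pending:
            yield from pending.popleft().result()


def _emit_single(outcome: ReadOutcome, sinks: _Sinks, stats: RunStats,
                 demuxing: bool, log_handle) -> None:
    stats.reads_in += 1
    stats.bases_in += outcome.input_length
    if log_handle is not None:
        for line in outcome.log_lines:
            log_handle.write(line + "\n")
    if outcome.discard_reason == "uncalled":
        sinks.uncalled.write(outcome.record)
        stats._bump(stats.discarded, "uncalled")
        return
    if not outcome.passed_gate:
        if sinks.short is not None:
            sinks.short[0].write(outcome.record)
        stats._bump(stats.discarded, "too_short")
        return
    name = outcome.barcode_name if demuxing else ""
    sinks.writers[name][0].write(outcome.record)
    stats.bases_out += outcome.record.n_scored


def _emit_pair(outcome: PairOutcome, sinks: _Sinks, stats: RunStats,
               demuxing: bool, log_handle) -> None:
    for mate in (outcome.mate1, outcome.mate2):
        stats.reads_in += 1
        stats.bases_in += mate.input_length
        if log_handle is not None:
            for line in mate.log_lines:
                log_handle.write(line + "\n")
    if outcome.mate1.discard_reason == "uncalled" or \
            outcome.mate2.discard_reason == "uncalled":
        for mate in (outcome.mate1, outcome.mate2):
            sinks.uncalled.write(mate.record)
            stats._bump(stats.discarded, "uncalled")
        return
    if outcome.both_pass:
        name = outcome.barcode_name if demuxing else ""
        pair_sinks = sinks.writers[name]
        pair_sinks[0].write(outcome.mate1.record)
        pair_sinks[1].write(outcome.mate2.record)
        stats.bases_out += (
            outcome.mate1.record.n_scored + outcome.mate2.record.n_scored
        )
        return
    # broken pair: neither mate enters the paired sinks
    for mate_idx, mate in enumerate((outcome.mate1, outcome.mate2)):
        if mate.passed_gate:
            if sinks.single is not None:
                sinks.single.write(mate.record)
                stats._bump(stats.written, "single")
                stats.bases_out += mate.record.n_scored
            else:
                stats._bump(stats.discarded, "orphaned")
        else:
            if sinks.short is not None:
                sinks.short[mate_idx].write(mate.record)
            stats._bump(stats.discarded, "too_short")
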