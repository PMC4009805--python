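"""Seeded generator of barcoded synthetic reads with ground truth.

The generator emulates a demultiplexing experiment: a known barcode is
planted at the 5' end of every read, optionally mutated by a simple
per-position error model (substitutions, insertions, deletions and
uncalled bases, each an independent Bernoulli event per position), and
followed by a random insert; an adapter suffix can be appended when the
insert is shorter than the read.  Barcodes are distributed round-robin,
so a multiple of ``len(barcode_set)`` reads plants every barcode equally
often.  A truth table records, per read, the planted barcode, insert and
every introduced error, which lets :func:`evaluate` score a
demultiplexing run exactly.

The error model is deliberately flat (no 3' quality ramp, no
homopolymer bias): it gives controllable error classes for verification,
not a faithful instrument profile.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import colorspace
from .demux import UNASSIGNED
from .errors import ConfigError, EvaluationError
from .seqio import SequenceRecord, Space

_BASES = "ACGT"

#: Default simulated sample sheet: eight 7-mer barcodes, pairwise
#: Hamming distance >= 5, so one substitution is always correctable and
#: two substitutions can never reach a wrong barcode.
DEFAULT_BARCODES: tuple[str, ...] = (
    "CCAAAGT",
    "AATTACG",
    "TGGAATA",
    "GTCAACC",
    "ACCCGCA",
    "GGCTCGA",
    "AAACTGC",
    "GGAGAAG",
)


@dataclass(frozen=True)
class SimConfig:
    """Generation settings.

    Rates are per-position probabilities applied to the planted barcode;
    ``exact_substitutions`` overrides the rates with exactly k
    substitutions at distinct positions of every barcode (for
    deterministic error budgets).  ``base_quality`` is the constant
    Phred value written for every position.
    """

    n_reads: int = 1000
    read_length: int = 36
    barcode_set: tuple[str, ...] = DEFAULT_BARCODES
    adapter: str | None = None
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    n_rate: float = 0.0
    exact_substitutions: int | None = None
    seed: int = 1
    space: Space = Space.LETTER
    base_quality: int = 35
    min_insert: int = 10
    max_insert: int | None = None

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate, self.n_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("error rates must lie in [0, 1]")
        if any(len(b) > self.read_length for b in self.barcode_set):
            raise ConfigError("barcode longer than read length")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated read."""

    read_id: str
    barcode_name: str
    barcode_seq: str
    insert: str
    edits: tuple[str, ...]  # e.g. ("sub@2:A>G", "del@5:T", "ins@1:C", "n@0")


def _mutate_barcode(
    barcode: str, cfg: SimConfig, rng: random.Random
) -> tuple[str, tuple[str, ...]]:
    edits: list[str] = []
    if cfg.exact_substitutions is not None:
        k = cfg.exact_substitutions
        if k > len(barcode):
            raise ConfigError("more substitutions requested than positions")
        out = list(barcode)
        for pos in sorted(rng.sample(range(len(barcode)), k)):
            new = rng.choice([b for b in _BASES if b != out[pos]])
            edits.append(f"sub@{pos}:{out[pos]}>{new}")
            out[pos] = new
        return "".join(out), tuple(edits)
    out = []
    for pos, base in enumerate(barcode):
        if rng.random() < cfg.ins_rate:
            ins = rng.choice(_BASES)
            out.append(ins)
            edits.append(f"ins@{pos}:{ins}")
        r = rng.random()
        if r < cfg.del_rate:
            edits.append(f"del@{pos}:{base}")
            continue
        if r < cfg.del_rate + cfg.n_rate:
            out.append("N")
            edits.append(f"n@{pos}")
            continue
        if r < cfg.del_rate + cfg.n_rate + cfg.sub_rate:
            new = rng.choice([b for b in _BASES if b != base])
            out.append(new)
            edits.append(f"sub@{pos}:{base}>{new}")
            continue
        out.append(base)
    return "".join(out), tuple(edits)


def _random_insert(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def generate(cfg: SimConfig) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate barcoded single-end reads plus their truth table.

    Deterministic for a fixed config (byte-identical across runs).
    """
    rng = random.Random(cfg.seed)
    names = [f"bc{i + 1}" for i in range(len(cfg.barcode_set))]
    reads: list[SequenceRecord] = []
    truth: list[TruthRecord] = []
    for i in range(cfg.n_reads):
        which = i % len(cfg.barcode_set)
        barcode = cfg.barcode_set[which]
        mutated, edits = _mutate_barcode(barcode, cfg, rng)
        insert_len = max(cfg.read_length - len(mutated), 0)
        insert = _random_insert(insert_len, rng)
        seq = (mutated + insert)[: cfg.read_length]
        read_id = f"sim_{i}"
        truth.append(TruthRecord(read_id, names[which], barcode, insert, edits))
        reads.append(_finalize(read_id, seq, cfg))
    return reads, truth


def generate_pairs(
    cfg: SimConfig,
) -> tuple[
    list[tuple[SequenceRecord, SequenceRecord]], list[TruthRecord]
]:
    """Generate read pairs whose mates read through into an adapter.

    Each fragment has a random insert length in
    ``[min_insert, max_insert]``; when the insert is shorter than the
    read length, the remainder of each mate is filled with the adapter
    sequence (so adapter trimming recovers the insert, and short inserts
    fall below typical length gates).  Requires ``adapter``.
    """
    if cfg.adapter is None:
        raise ConfigError("generate_pairs requires an adapter sequence")
    rng = random.Random(cfg.seed)
    max_insert = cfg.max_insert if cfg.max_insert is not None \
        else cfg.read_length + 10
    pairs = []
    truth = []
    for i in range(cfg.n_reads):
        insert_len = rng.randint(cfg.min_insert, max_insert)
        insert = _random_insert(insert_len, rng)
        read_id = f"simpair_{i}"
        mates = []
        for mate_seq in (insert, _revcomp(insert)):
            seq = mate_seq[: cfg.read_length]
            if len(seq) < cfg.read_length:
                fill = (cfg.adapter * cfg.read_length)[
                    : cfg.read_length - len(seq)
                ]
                seq += fill
            mates.append(_finalize(read_id, seq, cfg))
        pairs.append((mates[0], mates[1]))
        truth.append(TruthRecord(read_id, "", "", insert, ()))
    return pairs, truth


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def _finalize(read_id: str, seq: str, cfg: SimConfig) -> SequenceRecord:
    if cfg.space is Space.COLOR:
        if "N" in seq:
            encoded = []
            prev = None
            for base in seq:  # N encodes as uncalled color on both flanks
                if prev is None:
                    encoded.append(base if base != "N" else "A")
                elif base == "N" or prev == "N":
                    encoded.append(".")
                else:
                    encoded.append(
                        colorspace.TRANSITIONS[(prev, base)]
                    )
                prev = base
            cs = "".join(encoded)
        else:
            cs = colorspace.encode(seq)
        quals = tuple([cfg.base_quality] * (len(cs) - 1))
        return SequenceRecord(read_id, cs, quals, Space.COLOR)
    quals = tuple([cfg.base_quality] * len(seq))
    return SequenceRecord(read_id, seq, quals, Space.LETTER)


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    """Truth table as a DataFrame (column ``edits`` is ';'-joined)."""
    return pd.DataFrame(
        {
            "read_id": [t.read_id for t in truth],
            "barcode": [t.barcode_name for t in truth],
            "insert": [t.insert for t in truth],
            "edits": [";".join(t.edits) for t in truth],
        }
    )


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    truth_frame(truth).to_csv(path, sep="\t", index=False)


def evaluate(
    truth: list[TruthRecord], assignments: dict[str, str]
) -> tuple[int, int, pd.DataFrame]:
    """Score demultiplexing output against the truth table.

    ``assignments`` maps read id to assigned barcode name (UNASSIGNED
    for the reject stream).  Returns (misassigned, unassigned,
    confusion matrix) where the matrix rows are true barcodes and
    columns assigned ones.  Every truth read must have an assignment.
    """
    missing = [t.read_id for t in truth if t.read_id not in assignments]
    if missing:
        raise EvaluationError(
            f"{len(missing)} truth reads missing from demux output "
            f"(first: {missing[0]!r})"
        )
    rows = []
    for t in truth:
        rows.append((t.barcode_name, assignments[t.read_id]))
    frame = pd.DataFrame(rows, columns=["true", "assigned"])
    confusion = pd.crosstab(frame["true"], frame["assigned"])
    unassigned = int((frame["assigned"] == UNASSIGNED).sum())
    misassigned = int(
        (
            (frame["assigned"] != frame["true"])
            & (frame["assigned"] != UNASSIGNED)
        ).sum()
    )
    return misassigned, unassigned, confusion
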