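"""Reading and writing of sequence records.

Supported containers: FASTA, FASTQ (Sanger offset 33 and Illumina 1.3/1.5
offset 64), SOLiD csfasta with an optional companion ``.qual`` file, and
csfastq (FASTQ layout with a color-space sequence line).  Letter-space
FASTA/FASTQ goes through Biopython; the SOLiD formats are parsed here
because no installed library reads them.  Files ending in ``.gz`` are
read and written through gzip transparently.

Pairing of two read files is positional: the i-th record of file 1 is
paired with the i-th record of file 2.  Read ids are not compared, since
mate-id conventions (``/1``, ``/2``, whitespace comments) vary between
pipelines.
"""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, PairingError, ParseError

_LETTER_BASES = set("ACGTN")
_COLOR_CHARS = set("0123.")


class Space(Enum):
    """Sequence encoding: nucleotide letters or SOLiD color digits."""

    LETTER = "letter"
    COLOR = "color"


class Container(Enum):
    FASTA = "fasta"
    FASTQ = "fastq"
    CSFASTA = "csfasta"
    CSFASTQ = "csfastq"


@dataclass(frozen=True)
class SequenceRecord:
    """One sequencing read.

    ``sequence`` is letters over {A,C,G,T,N} in letter space, or an
    optional primer base followed by color digits {0,1,2,3,.} in color
    space (a primer-less color record is all digits).  ``qualities``, if
    present, holds one Phred value per *scored* position: every letter in
    letter space, every color in color space (the primer base is not
    scored).  Records produced by trimming may be empty; file readers
    reject empty records.
    """

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    space: Space = Space.LETTER

    def __post_init__(self) -> None:
        if self.qualities is not None:
            object.__setattr__(self, "qualities", tuple(self.qualities))
            if any(q < 0 for q in self.qualities):
                raise ValueError(f"negative quality in record {self.id!r}")
            if len(self.qualities) != self.n_scored:
                raise ValueError(
                    f"record {self.id!r}: {len(self.qualities)} qualities for "
                    f"{self.n_scored} scored positions"
                )

    @property
    def has_primer(self) -> bool:
        """True for a color-space record that still carries its primer base."""
        return (
            self.space is Space.COLOR
            and len(self.sequence) > 0
            and self.sequence[0] in "ACGT"
        )

    @property
    def colors(self) -> str:
        """Color digits of a color-space record (primer stripped)."""
        if self.space is not Space.COLOR:
            raise ValueError("letter-space record has no colors")
        return self.sequence[1:] if self.has_primer else self.sequence

    @property
    def n_scored(self) -> int:
        """Number of positions that carry a quality value."""
        if self.space is Space.COLOR:
            return len(self.colors)
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadFormat:
    """A container format plus quality-encoding dialect."""

    container: Container
    quality_offset: int = 33
    dialect_name: str = "fastq-sanger"

    def __post_init__(self) -> None:
        if self.quality_offset not in (33, 64):
            raise ConfigError(
                f"quality offset must be 33 or 64, got {self.quality_offset}"
            )

    @property
    def space(self) -> Space:
        if self.container in (Container.CSFASTA, Container.CSFASTQ):
            return Space.COLOR
        return Space.LETTER

    @property
    def has_qualities(self) -> bool:
        return self.container in (Container.FASTQ, Container.CSFASTQ)

    @property
    def extension(self) -> str:
        return self.container.value

    @classmethod
    def from_dialect(cls, name: str) -> "ReadFormat":
        """Resolve a dialect name such as ``fastq-i1.3`` to a format."""
        known = {
            "fasta": cls(Container.FASTA, 33, "fasta"),
            "fastq": cls(Container.FASTQ, 33, "fastq-sanger"),
            "fastq-sanger": cls(Container.FASTQ, 33, "fastq-sanger"),
            "fastq-i1.3": cls(Container.FASTQ, 64, "fastq-i1.3"),
            "fastq-i1.5": cls(Container.FASTQ, 64, "fastq-i1.5"),
            "csfasta": cls(Container.CSFASTA, 33, "csfasta"),
            "csfastq": cls(Container.CSFASTQ, 33, "csfastq"),
        }
        try:
            return known[name]
        except KeyError:
            raise ConfigError(
                f"unknown format dialect {name!r}; choose from "
                f"{sorted(known)}"
            ) from None


FASTA = ReadFormat.from_dialect("fasta")
FASTQ_SANGER = ReadFormat.from_dialect("fastq-sanger")


def _open(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# readers


def _read_letter(path: str | Path, fmt: ReadFormat) -> Iterator[SequenceRecord]:
    bio_format = "fasta" if fmt.container is Container.FASTA else (
        "fastq-sanger" if fmt.quality_offset == 33 else "fastq-illumina"
    )
    with _open(path, "r") as handle:
        parser = SeqIO.parse(handle, bio_format)
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed record at index {index}: {exc}"
                ) from exc
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"{path}: empty sequence at index {index}")
            quals = None
            if fmt.container is Container.FASTQ:
                quals = tuple(rec.letter_annotations["phred_quality"])
            yield SequenceRecord(rec.id, seq, quals, Space.LETTER)
            index += 1


def _parse_csfasta_like(handle: IO[str], path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, payload-line) pairs from a '>'-delimited SOLiD file."""
    name: str | None = None
    index = 0
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None:
                raise ParseError(
                    f"{path}: header without sequence at record index {index}"
                )
            name = line[1:].split()[0] if len(line) > 1 else ""
        else:
            if name is None:
                raise ParseError(
                    f"{path}: data line outside a record at index {index}"
                )
            yield name, line
            name = None
            index += 1
    if name is not None:
        raise ParseError(f"{path}: truncated final record {name!r}")


def _read_csfasta(
    path: str | Path, qual_path: str | Path | None
) -> Iterator[SequenceRecord]:
    qual_iter: Iterator[tuple[str, str]] | None = None
    qual_handle: IO[str] | None = None
    if qual_path is not None:
        qual_handle = _open(qual_path, "r")
        qual_iter = _parse_csfasta_like(qual_handle, qual_path)
    try:
        with _open(path, "r") as handle:
            for index, (name, seq) in enumerate(
                _parse_csfasta_like(handle, path)
            ):
                _validate_color(seq, path, index)
                quals = None
                if qual_iter is not None:
                    try:
                        qname, qline = next(qual_iter)
                    except StopIteration:
                        raise ParseError(
                            f"{qual_path}: fewer quality records than reads"
                        ) from None
                    quals = tuple(int(tok) for tok in qline.split())
                    n_colors = len(seq) - 1 if seq[0] in "ACGT" else len(seq)
                    if len(quals) != n_colors:
                        raise ParseError(
                            f"{qual_path}: record {qname!r} (index {index}) has "
                            f"{len(quals)} qualities for {n_colors} colors"
                        )
                yield SequenceRecord(name, seq, quals, Space.COLOR)
            if qual_iter is not None and next(qual_iter, None) is not None:
                raise ParseError(f"{qual_path}: more quality records than reads")
    finally:
        if qual_handle is not None:
            qual_handle.close()


def _validate_color(seq: str, path: str | Path, index: int) -> None:
    body = seq[1:] if seq and seq[0] in "ACGT" else seq
    if not seq:
        raise ParseError(f"{path}: empty sequence at index {index}")
    bad = set(body) - _COLOR_CHARS
    if bad:
        raise ParseError(
            f"{path}: invalid color characters {sorted(bad)} at index {index}"
        )


def _read_csfastq(path: str | Path, fmt: ReadFormat) -> Iterator[SequenceRecord]:
    with _open(path, "r") as handle:
        index = 0
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(
                    f"{path}: record index {index}: expected '@', got "
                    f"{header[:20]!r}"
                )
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ParseError(
                    f"{path}: record index {index}: missing '+' separator"
                )
            _validate_color(seq, path, index)
            n_colors = len(seq) - 1 if seq[0] in "ACGT" else len(seq)
            if len(qual) != n_colors:
                raise ParseError(
                    f"{path}: record index {index}: {len(qual)} quality "
                    f"characters for {n_colors} colors"
                )
            quals = tuple(ord(c) - fmt.quality_offset for c in qual)
            if any(q < 0 for q in quals):
                raise ParseError(
                    f"{path}: record index {index}: quality below offset "
                    f"{fmt.quality_offset}"
                )
            yield SequenceRecord(header[1:].split()[0], seq, quals, Space.COLOR)
            index += 1


def read_records(
    path: str | Path,
    fmt: ReadFormat,
    qual_path: str | Path | None = None,
) -> Iterator[SequenceRecord]:
    """Stream records from ``path`` in file order.

    ``qual_path`` names the companion ``.qual`` file for csfasta input;
    it is ignored for other containers.
    """
    if fmt.container in (Container.FASTA, Container.FASTQ):
        return _read_letter(path, fmt)
    if fmt.container is Container.CSFASTA:
        return _read_csfasta(path, qual_path)
    return _read_csfastq(path, fmt)


# ---------------------------------------------------------------------------
# writers


class RecordWriter:
    """Streaming writer for one output file (plus .qual for csfasta)."""

    def __init__(self, path: str | Path, fmt: ReadFormat,
                 write_qual: bool = False):
        self.path = Path(path)
        self.fmt = fmt
        self.count = 0
        self._handle = _open(path, "w")
        self._qual_handle: IO[str] | None = None
        if fmt.container is Container.CSFASTA and write_qual:
            self._qual_handle = _open(self.path.with_suffix(".qual"), "w")

    def write(self, record: SequenceRecord) -> None:
        fmt = self.fmt
        if (record.space is Space.COLOR) != (fmt.space is Space.COLOR):
            raise ConfigError(
                f"record {record.id!r} is {record.space.value}-space but the "
                f"output format is {fmt.container.value}"
            )
        if fmt.container is Container.FASTA:
            self._handle.write(f">{record.id}\n{record.sequence}\n")
        elif fmt.container is Container.FASTQ:
            if record.qualities is None:
                raise ConfigError(
                    f"record {record.id!r} has no qualities for FASTQ output"
                )
            bio = SeqRecord(Seq(record.sequence), id=record.id, description="")
            bio.letter_annotations["phred_quality"] = list(record.qualities)
            bio_format = (
                "fastq-sanger" if fmt.quality_offset == 33 else "fastq-illumina"
            )
            self._handle.write(bio.format(bio_format))
        elif fmt.container is Container.CSFASTA:
            self._handle.write(f">{record.id}\n{record.sequence}\n")
            if self._qual_handle is not None:
                quals = record.qualities or ()
                self._qual_handle.write(
                    f">{record.id}\n{' '.join(map(str, quals))}\n"
                )
        else:  # CSFASTQ
            if record.qualities is None:
                raise ConfigError(
                    f"record {record.id!r} has no qualities for csfastq output"
                )
            qual = "".join(
                chr(q + fmt.quality_offset) for q in record.qualities
            )
            self._handle.write(f"@{record.id}\n{record.sequence}\n+\n{qual}\n")
        self.count += 1

    def close(self) -> None:
        self._handle.close()
        if self._qual_handle is not None:
            self._qual_handle.close()

    def __enter__(self) -> "RecordWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_records(
    records: Iterable[SequenceRecord],
    path: str | Path,
    fmt: ReadFormat,
    write_qual: bool = False,
) -> int:
    """Write records to ``path``; returns the number written.

    Output re-parses to the identical record list (round-trip identity).
    """
    with RecordWriter(path, fmt, write_qual=write_qual) as writer:
        for record in records:
            writer.write(record)
        return writer.count


def read_pairs(
    path1: str | Path, path2: str | Path, fmt: ReadFormat
) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
    """Pair the i-th record of ``path1`` with the i-th of ``path2``.

    Raises :class:`PairingError` (reporting both counts) when the files
    disagree on record count.
    """
    it1, it2 = read_records(path1, fmt), read_records(path2, fmt)
    n = 0
    while True:
        r1, r2 = next(it1, None), next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            n1 = n + sum(1 for _ in it1) + (r1 is not None)
            n2 = n + sum(1 for _ in it2) + (r2 is not None)
            raise PairingError(
                f"paired files differ in record count: {path1} has {n1}, "
                f"{path2} has {n2}"
            )
        yield r1, r2
        n += 1
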