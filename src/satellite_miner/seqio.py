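"""FASTQ/FASTA I/O for paired-end reads.

Reads are carried as :class:`Read` (sequence plus integer Phred scores) and
mate pairs as :class:`ReadPair`.  Parsing is built on Biopython's
``FastqGeneralIterator``; this module adds the pair-aware contract the rest
of the pipeline relies on: a configurable Phred offset (+33 by default, +64
selectable), mate-identifier normalization, and strict parity checking so
that the two files always describe the same templates in the same order.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

MAX_PHRED = 93
_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqFormatError(ValueError):
    """Malformed FASTQ record."""


class PairParityError(ValueError):
    """Mate files disagree in record count or record identifiers."""


class QualityEncodingError(ValueError):
    """Quality character incompatible with the declared Phred offset."""


@dataclass
class Read:
    """One sequencing read: identifier, bases, and per-base Phred scores."""

    id: str
    seq: str
    quals: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.id!r}: invalid bases {sorted(bad)}")
        for q in self.quals:
            if not 0 <= q <= MAX_PHRED:
                raise ValueError(f"read {self.id!r}: Phred score {q} outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> "Read":
        """Contiguous sub-read over [start, end)."""
        return Read(self.id, self.seq[start:end], self.quals[start:end])

    def reverse_complement(self) -> "Read":
        return Read(self.id, reverse_complement(self.seq), self.quals[::-1])


@dataclass
class ReadPair:
    """Mate-1/mate-2 reads from one template; the unit of trimming and assembly."""

    r1: Read
    r2: Read
    pair_id: str

    def __post_init__(self) -> None:
        if normalize_read_id(self.r1.id) != normalize_read_id(self.r2.id):
            raise PairParityError(
                f"mate identifiers disagree after normalization: "
                f"{self.r1.id!r} vs {self.r2.id!r}"
            )


_MATE_SUFFIX = re.compile(r"/[12]$")


def normalize_read_id(title: str) -> str:
    """Normalize a FASTQ title to its template identifier.

    Strips Casava 1.8 space-delimited mate tags (everything after the first
    whitespace) and classic trailing ``/1`` / ``/2`` mate suffixes.
    """
    head = title.split(None, 1)[0] if title else title
    return _MATE_SUFFIX.sub("", head)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _decode_quals(qual_str: str, offset: int, read_id: str) -> list[int]:
    quals = []
    for ch in qual_str:
        q = ord(ch) - offset
        if q < 0:
            raise QualityEncodingError(
                f"read {read_id!r}: quality character {ch!r} (ASCII {ord(ch)}) "
                f"below Phred offset {offset}"
            )
        if q > MAX_PHRED:
            raise QualityEncodingError(
                f"read {read_id!r}: quality character {ch!r} decodes to {q} > {MAX_PHRED} "
                f"at offset {offset}"
            )
        quals.append(q)
    return quals


def _iter_fastq(path: str | Path, offset: int) -> Iterator[tuple[str, Read]]:
    """Yield (raw_title, Read) from a 4-line FASTQ file."""
    with _open_text(path) as handle:
        record_idx = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = normalize_read_id(title)
                seq = seq.upper()
                if set(seq) - _VALID_BASES:
                    raise FastqFormatError(
                        f"{path}: invalid base in record near line {4 * record_idx + 2} "
                        f"(read {read_id!r})"
                    )
                yield title, Read(read_id, seq, _decode_quals(qual, offset, read_id))
                record_idx += 1
        except ValueError as exc:
            if isinstance(exc, (FastqFormatError, QualityEncodingError, PairParityError)):
                raise
            raise FastqFormatError(
                f"{path}: malformed FASTQ record near line {4 * record_idx + 1}: {exc}"
            ) from exc


def read_fastq(path: str | Path, quality_offset: int = 33) -> Iterator[Read]:
    """Iterate over single-end reads in a FASTQ file."""
    for _title, read in _iter_fastq(path, quality_offset):
        yield read


def read_paired_fastq(
    path1: str | Path, path2: str | Path, quality_offset: int = 33
) -> Iterator[ReadPair]:
    """Iterate over mate pairs from two parallel FASTQ files.

    Records are paired positionally; identifiers must agree after mate-suffix
    normalization.  Raises :class:`PairParityError` on count or id mismatch.
    """
    it1 = _iter_fastq(path1, quality_offset)
    it2 = _iter_fastq(path2, quality_offset)
    n = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            return
        if rec1 is None or rec2 is None:
            longer = path2 if rec1 is None else path1
            raise PairParityError(
                f"unequal record counts: {longer} has more than {n} records, "
                f"its mate file does not"
            )
        _t1, r1 = rec1
        _t2, r2 = rec2
        if r1.id != r2.id:
            raise PairParityError(
                f"record {n + 1}: mate identifiers disagree after normalization: "
                f"{r1.id!r} vs {r2.id!r}"
            )
        yield ReadPair(r1, r2, r1.id)
        n += 1


def _format_record(read: Read, mate: int, pair_id: str, offset: int) -> str:
    qual_str = "".join(chr(q + offset) for q in read.quals)
    return f"@{pair_id}/{mate}\n{read.seq}\n+\n{qual_str}\n"


def write_paired_fastq(
    pairs: Iterable[ReadPair],
    path1: str | Path,
    path2: str | Path,
    quality_offset: int = 33,
) -> int:
    """Write mate pairs to two FASTQ files with ``/1`` and ``/2`` suffixes.

    Returns the number of pairs written.  Round-trips exactly through
    :func:`read_paired_fastq`.
    """
    n = 0
    with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
        for pair in pairs:
            h1.write(_format_record(pair.r1, 1, pair.pair_id, quality_offset))
            h2.write(_format_record(pair.r2, 2, pair.pair_id, quality_offset))
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> int:
    """Write an {id: sequence} mapping as FASTA; returns record count."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with _open_text(path, "wt") as handle:
        return SeqIO.write(records, handle, "fasta")
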