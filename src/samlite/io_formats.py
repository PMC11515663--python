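"""Readers and writers for the plain-text formats the pipeline touches:
FASTA and FASTQ (plain or gzip) and TSV tables.

Parsing is delegated to Biopython's low-level iterators; this module adds
gzip awareness, a uniform record type and error messages that locate the
offending record.  All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    sequence: str
    quality: Optional[str] = None


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, encoding="ascii", newline=None)


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Stream FASTA records in file order; multi-line sequences are joined
    and CRLF line endings tolerated.  The record id is the first
    whitespace-delimited token of the description line."""
    with _open_text(path) as fh:
        first = fh.read(1)
        if first and first not in (">", ";"):
            raise ValueError(f"{path}: line 1: sequence data before any '>' header")
        fh.seek(0)
        for n, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
            title = title.strip()
            if not title:
                raise ValueError(f"{path}: record {n}: empty description line")
            yield SequenceRecord(
                id=title.split()[0],
                description=title,
                sequence=seq.strip().replace("\r", ""),
            )


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Stream FASTQ records (4-line format, '+' line with or without a
    repeated id).  Raises on truncated or malformed records, naming the
    record index."""
    n = 0
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                title = title.strip()
                yield SequenceRecord(
                    id=title.split()[0] if title else "",
                    description=title,
                    sequence=seq,
                    quality=qual,
                )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ at record {n + 1}: {exc}") from exc


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write ``(id, sequence, quality)`` records; gzip if path ends in .gz."""
    path = Path(path)
    if path.suffix == ".gz":
        # mtime pinned and filename omitted so identical content gives
        # identical bytes
        fh = io.TextIOWrapper(
            gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0),
            encoding="ascii",
        )
    else:
        fh = open(path, "w", encoding="ascii")
    with fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def _format_cell(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_tsv(rows: Iterable[Sequence], header: Sequence[str], path) -> None:
    """Write a rectangular TSV with a header row; floats are rendered with 6
    significant digits for stable round-trips."""
    width = len(header)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(str(h) for h in header) + "\n")
        for i, row in enumerate(rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged row {i}: expected {width} fields, got {len(row)}"
                )
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def read_tsv(path) -> tuple[list[str], list[list[str]]]:
    """Read a TSV written by :func:`write_tsv` back as (header, rows of
    strings)."""
    with open(path, encoding="utf-8") as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        return [], []
    header = lines[0].split("\t")
    return header, [line.split("\t") for line in lines[1:]]
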