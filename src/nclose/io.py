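"""FASTA/FASTQ reading and writing (plain or gzip) via Biopython."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file (detected by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(handle: IO[str]) -> str:
    head = handle.read(1)
    handle.seek(0)
    if head == ">":
        return "fasta"
    if head == "@":
        return "fastq"
    raise ValueError("cannot determine sequence format (expected FASTA or FASTQ)")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, uppercase sequence) pairs."""
    with open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def iter_reads(paths: Iterable[str | Path]) -> Iterator[str]:
    """Stream uppercase read sequences from FASTA/FASTQ files, gzip or not."""
    for path in paths:
        with open_text(path) as fh:
            fmt = _sniff_format(fh)
            for rec in SeqIO.parse(fh, fmt):
                yield str(rec.seq).upper()


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA.  The id may contain a
    description after the first space."""
    seq_records = []
    for name, seq in records:
        ident, _, desc = name.partition(" ")
        seq_records.append(SeqRecord(Seq(seq), id=ident, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def write_fastq_gz(path: str | Path, reads: Iterable[tuple[str, str]],
                   quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as gzip FASTQ with constant quality."""
    with gzip.open(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
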