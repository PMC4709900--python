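"""FASTQ/FASTA I/O (plain or gzip), 4-line FASTQ records with Phred+33 qualities."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator


def open_text(path, mode: str = "rt") -> TextIO:
    """Open a possibly-gzipped text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t") or "r")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, seq, qual) from a FASTQ(.gz) file."""
    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (title, seq, qual) records as 4-line FASTQ; returns record count."""
    n = 0
    with open_text(path, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (name, seq) from a FASTA file; name is the first whitespace token."""
    name, chunks = None, []
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> int:
    n = 0
    with open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n
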