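"""FASTA/FASTQ reading and writing for strand pools and read sets."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def write_pool_fasta(strands, path) -> None:
    """Write designed strands, one record per strand, headers ``strand_<m>``."""
    with open(path, "w") as fh:
        for rec in strands:
            fh.write(f">strand_{rec.m}\n{rec.sequence}\n")


def read_fasta(path) -> list:
    with open(path) as fh:
        return [(name.split()[0], seq.upper()) for name, seq in SimpleFastaParser(fh)]


def read_fastq(path) -> list:
    with open(path) as fh:
        return [(name.split()[0], seq.upper()) for name, seq, _q in FastqGeneralIterator(fh)]


def read_seqs(path) -> list:
    """Sequences from a FASTA or FASTQ file, sniffed from the first byte."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return [seq for _n, seq in read_fasta(path)]
    if first == "@":
        return [seq for _n, seq in read_fastq(path)]
    raise IOError(f"{path}: not FASTA or FASTQ")


def write_fastq(seqs: Iterable[str], path, prefix: str = "read") -> None:
    """Write reads as 4-line FASTQ with a constant Q40 placeholder quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
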