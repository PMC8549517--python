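"""File input/output helpers: FASTA/FASTQ via Biopython, GFF3 and TSV writers.

All serialized coordinates are 1-based inclusive; in-memory interval
arithmetic inside the package is 0-based half-open unless a dataclass
documents otherwise.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_HEADER = "##gff-version 3"


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str]]) -> None:
    """Write ``(read_id, sequence)`` pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq_lengths(path: str | os.PathLike) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fastq")}


def write_gff3(path: str | os.PathLike, features: Iterable[tuple]) -> None:
    """Write GFF3 rows.

    ``features`` yields tuples ``(contig, source, ftype, start, end,
    score, strand, attributes)`` with 1-based inclusive coordinates and
    ``attributes`` a dict.
    """
    with open(path, "w") as fh:
        fh.write(GFF3_HEADER + "\n")
        for contig, source, ftype, start, end, score, strand, attrs in features:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            score_str = "." if score is None else f"{score:g}"
            fh.write(
                f"{contig}\t{source}\t{ftype}\t{start}\t{end}\t{score_str}\t{strand}\t.\t{attr_str}\n"
            )


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
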