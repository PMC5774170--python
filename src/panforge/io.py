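"""FASTA and TSV input/output.

FASTA reading goes through Biopython's SeqIO; sequences are upper-cased on
the way in and gzipped files (``.gz`` suffix) are transparently accepted.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
from Bio import SeqIO

from .model import Contig, Genome, TaxonomyRecord

__all__ = [
    "open_maybe_gzip",
    "read_genome",
    "read_fasta_records",
    "write_fasta",
    "read_abundance_tsv",
]


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta_records(path: str | Path) -> list[tuple[str, str]]:
    """All (id, upper-cased sequence) records of a (possibly gzipped) FASTA."""
    with open_maybe_gzip(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def read_genome(
    path: str | Path,
    accession: str | None = None,
    taxonomy: TaxonomyRecord | None = None,
    is_representative: bool = False,
) -> Genome:
    """Read a multi-FASTA assembly into a :class:`Genome`.

    The accession defaults to the file name stripped of FASTA/gzip suffixes.
    A file that yields no records raises, so a malformed assembly aborts a
    build instead of being silently skipped.
    """
    path = Path(path)
    records = read_fasta_records(path)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if accession is None:
        accession = path.name
        for suffix in (".gz", ".fa", ".fasta", ".fna"):
            if accession.endswith(suffix):
                accession = accession[: -len(suffix)]
    return Genome(
        accession=accession,
        contigs=[Contig(rid, seq) for rid, seq in records],
        taxonomy=taxonomy or TaxonomyRecord(),
        is_representative=is_representative,
    )


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 80
) -> None:
    """Write (header, sequence) pairs as FASTA with fixed line width."""
    with open_maybe_gzip(path, "wt") as out:
        for header, seq in records:
            out.write(f">{header}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    """Two-column (label, abundance) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["label", "abundance"])
    df["abundance"] = df["abundance"].astype(float)
    return df
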