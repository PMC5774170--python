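"""Core domain objects shared across the toolkit.

A :class:`Genome` is the unit everything iterates over: a named, ordered set
of contigs with optional taxonomy metadata and a representative-genome flag.
Coordinates are 0-based, half-open everywhere in the library; 1-based
coordinates appear only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class Interval:
    """Half-open interval [start, end) on a named contig."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Contig:
    """A single FASTA record: id plus an upper-case DNA sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyRecord:
    """Taxonomic metadata attached to a genome.

    ``lineage`` is an ordered sequence of (rank, name) pairs, e.g.
    ``(("k", "Bacteria"), ("p", "Bacteroidetes"))``.
    """

    taxid: str = ""
    species_taxid: str = ""
    lineage: tuple[tuple[str, str], ...] = ()
    organism_name: str = ""

    def __post_init__(self) -> None:
        ranks = [r for r, _ in self.lineage]
        if len(ranks) != len(set(ranks)):
            raise ValueError("lineage ranks must be unique")


@dataclass
class Genome:
    """A strain genome: accession, ordered contigs, taxonomy, rep flag."""

    accession: str
    contigs: list[Contig]
    taxonomy: TaxonomyRecord = field(default_factory=TaxonomyRecord)
    is_representative: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("genome accession must be non-empty")
        if not self.contigs:
            raise ValueError(f"genome {self.accession!r} has no contigs")
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contig ids in genome {self.accession!r}")

    @property
    def total_size(self) -> int:
        return sum(c.length for c in self.contigs)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement; bases outside ACGTN pass through unchanged."""
    return sequence.translate(_COMPLEMENT)[::-1]
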