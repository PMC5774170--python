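"""Iterative pan-genome construction.

The algorithm: order the conspecific strain genomes (designated
representative first, otherwise the largest assembly; the remainder in
descending total size), seed the pan-genome with the first genome's contigs
verbatim, then for every further strain align it to the current pan-genome
and append only the query-exclusive regions as new contigs.  The standing
reference is only ever extended — never trimmed, edited, or reordered — so
the pan-genome of iteration *i* is a byte-identical prefix of iteration
*i+1*.  A database can therefore be updated with a newly sequenced strain by
a single additional alignment.

Species with very many sequenced strains are capped: by default only the
representative plus the 49 largest strain genomes enter the build (19 for
the fungal preset).  Contigs shorter than ``min_contig_len`` (default
1000 bp, boundary value kept) are removed once, after the final iteration.

Each appended region is padded with a short flank of aligned context
(``flank``, default 25 bp) on both sides so that k-mers spanning the
junction between shared and novel sequence remain present in the pan-genome;
the provenance record stores the padded source interval, hence every
appended contig is a verbatim substring of its source strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .alignment import AlignParams, align_pair, query_exclusive_regions
from .model import Contig, Genome, Interval

__all__ = [
    "BuildParams",
    "FUNGAL_MAX_STRAINS",
    "ProvenanceRecord",
    "PanContig",
    "PanGenome",
    "order_genomes",
    "cap_strains",
    "iterate_pangenome",
    "build_pangenome",
    "filter_short_contigs",
    "update_pangenome",
    "write_pangenome",
    "read_pangenome",
]

#: Strain cap for fungal species (representative + 19 largest).
FUNGAL_MAX_STRAINS = 20


@dataclass(frozen=True)
class BuildParams:
    """Parameters of a pan-genome build.

    max_strains: cap on genomes entering the build, representative included
        (default 50: the representative plus the 49 largest; use
        :data:`FUNGAL_MAX_STRAINS` for fungi).
    min_contig_len: contigs shorter than this are removed from the final
        pan-genome ("shorter than" is literal: the boundary length survives).
    flank: bp of aligned context retained on each side of an appended
        exclusive region, keeping junction k-mers in the database.
    """

    align: AlignParams = field(default_factory=AlignParams)
    max_strains: int = 50
    min_contig_len: int = 1000
    flank: int = 25

    def __post_init__(self) -> None:
        if self.max_strains < 1:
            raise ValueError("max_strains must be >= 1")
        if self.min_contig_len < 0 or self.flank < 0:
            raise ValueError("min_contig_len and flank must be >= 0")


@dataclass(frozen=True)
class ProvenanceRecord:
    """Where a pan-genome contig came from: strain, contig, interval, iteration."""

    source_accession: str
    source_contig: str
    source_interval: Interval
    iteration: int

    def __post_init__(self) -> None:
        if self.iteration < 0:
            raise ValueError("iteration must be >= 0")


@dataclass(frozen=True)
class PanContig:
    id: str
    sequence: str
    provenance: ProvenanceRecord

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"pan-genome contig {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PanGenome:
    """Ordered pan-genome contigs; order is appending order (seed first)."""

    species_taxid: str
    contigs: list[PanContig]
    genomes_used: list[str]

    @property
    def total_size(self) -> int:
        return sum(c.length for c in self.contigs)

    def as_genome(self, accession: str = "pangenome") -> Genome:
        """View as a plain :class:`Genome`, e.g. to serve as alignment reference."""
        return Genome(
            accession=accession,
            contigs=[Contig(c.id, c.sequence) for c in self.contigs],
        )


def order_genomes(genomes: list[Genome]) -> list[Genome]:
    """Representative first, then strictly descending total size.

    Without a designated representative the largest genome leads.  Size ties
    break lexicographically by accession.  More than one representative is an
    error.
    """
    if not genomes:
        raise ValueError("no genomes to order")
    reps = [g for g in genomes if g.is_representative]
    if len(reps) > 1:
        raise ValueError("multiple representatives")
    rest = sorted(
        (g for g in genomes if not g.is_representative),
        key=lambda g: (-g.total_size, g.accession),
    )
    return reps + rest


def cap_strains(ordered: list[Genome], max_strains: int) -> list[Genome]:
    """Truncate an ordered genome list to at most ``max_strains`` entries.

    The first element (representative or largest) is always kept.
    """
    if max_strains < 1:
        raise ValueError("max_strains must be >= 1")
    return list(ordered[:max_strains])


def _seed_pangenome(genome: Genome, species_taxid: str) -> PanGenome:
    contigs = [
        PanContig(
            id=c.id,
            sequence=c.sequence,
            provenance=ProvenanceRecord(
                genome.accession, c.id, Interval(c.id, 0, c.length), 0
            ),
        )
        for c in genome.contigs
        if c.length > 0
    ]
    return PanGenome(species_taxid, contigs, [genome.accession])


def _append_exclusive(
    pan: PanGenome, genome: Genome, params: BuildParams, iteration: int
) -> PanGenome:
    """One alignment iteration: append the genome's exclusive regions to pan."""
    aln = align_pair(genome, pan.as_genome(), params.align)
    regions = query_exclusive_regions(genome, aln, params.align.min_exclusive_len)
    lengths = {c.id: c.length for c in genome.contigs}
    new_contigs = list(pan.contigs)
    for iv in regions:
        start = max(0, iv.start - params.flank)
        end = min(lengths[iv.contig_id], iv.end + params.flank)
        sequence = next(
            c.sequence for c in genome.contigs if c.id == iv.contig_id
        )[start:end]
        new_contigs.append(
            PanContig(
                id=f"{genome.accession}|{iv.contig_id}:{start}-{end}|iter{iteration}",
                sequence=sequence,
                provenance=ProvenanceRecord(
                    genome.accession,
                    iv.contig_id,
                    Interval(iv.contig_id, start, end),
                    iteration,
                ),
            )
        )
    return PanGenome(pan.species_taxid, new_contigs, pan.genomes_used + [genome.accession])


def iterate_pangenome(genomes: list[Genome], params: BuildParams) -> Iterator[PanGenome]:
    """Yield the (pre-filter) pan-genome after each iteration.

    Iteration 0 yields the seed (first ordered genome verbatim); each further
    iteration aligns the next strain against the current pan-genome and
    appends its exclusive regions.  Ordering and the strain cap are applied
    first.
    """
    if not genomes:
        raise ValueError("no genomes to build from")
    ordered = cap_strains(order_genomes(genomes), params.max_strains)
    species_taxid = ordered[0].taxonomy.species_taxid
    pan = _seed_pangenome(ordered[0], species_taxid)
    yield pan
    for iteration, genome in enumerate(ordered[1:], start=1):
        pan = _append_exclusive(pan, genome, params, iteration)
        yield pan


def build_pangenome(genomes: list[Genome], params: BuildParams | None = None) -> PanGenome:
    """Run all iterations and apply the final short-contig filter."""
    params = params or BuildParams()
    pan = None
    for pan in iterate_pangenome(genomes, params):
        pass
    assert pan is not None
    return filter_short_contigs(pan, params.min_contig_len)


def filter_short_contigs(pan: PanGenome, min_contig_len: int) -> PanGenome:
    """Drop contigs shorter than ``min_contig_len``; order is preserved."""
    kept = [c for c in pan.contigs if c.length >= min_contig_len]
    if not kept:
        warnings.warn("all pan-genome contigs fell below the length filter", stacklevel=2)
    return PanGenome(pan.species_taxid, kept, list(pan.genomes_used))


def update_pangenome(
    pan: PanGenome, new_genome: Genome, params: BuildParams | None = None
) -> PanGenome:
    """Incorporate one new strain by a single alignment.

    Existing contigs are untouched; exclusive regions of the new genome are
    appended (and only the newly appended contigs are subjected to the
    short-contig filter).
    """
    params = params or BuildParams()
    iteration = max((c.provenance.iteration for c in pan.contigs), default=0) + 1
    updated = _append_exclusive(pan, new_genome, params, iteration)
    n_old = len(pan.contigs)
    kept_new = [
        c for c in updated.contigs[n_old:] if c.length >= params.min_contig_len
    ]
    return PanGenome(pan.species_taxid, updated.contigs[:n_old] + kept_new,
                     updated.genomes_used)


def write_pangenome(pan: PanGenome, fasta_path, provenance_path=None) -> None:
    """Write the pan-genome FASTA and, optionally, the provenance TSV."""
    from .io import write_fasta

    write_fasta(((c.id, c.sequence) for c in pan.contigs), fasta_path)
    if provenance_path is not None:
        rows = [
            {
                "contig_id": c.id,
                "source_accession": c.provenance.source_accession,
                "source_contig": c.provenance.source_contig,
                "start": c.provenance.source_interval.start,
                "end": c.provenance.source_interval.end,
                "iteration": c.provenance.iteration,
                "genomes_used": ",".join(pan.genomes_used),
                "species_taxid": pan.species_taxid,
            }
            for c in pan.contigs
        ]
        pd.DataFrame(rows).to_csv(provenance_path, sep="\t", index=False)


def read_pangenome(fasta_path, provenance_path) -> PanGenome:
    """Re-load a pan-genome written by :func:`write_pangenome`."""
    from .io import read_fasta_records

    prov = pd.read_csv(provenance_path, sep="\t", dtype={"species_taxid": str})
    prov = prov.fillna("")
    by_id = {row.contig_id: row for row in prov.itertuples()}
    contigs = []
    for rid, seq in read_fasta_records(fasta_path):
        row = by_id[rid]
        contigs.append(
            PanContig(
                id=rid,
                sequence=seq,
                provenance=ProvenanceRecord(
                    row.source_accession,
                    row.source_contig,
                    Interval(row.source_contig, int(row.start), int(row.end)),
                    int(row.iteration),
                ),
            )
        )
    genomes_used = str(prov.iloc[0]["genomes_used"]).split(",") if len(prov) else []
    species_taxid = str(prov.iloc[0]["species_taxid"]) if len(prov) else ""
    return PanGenome(species_taxid, contigs, genomes_used)
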