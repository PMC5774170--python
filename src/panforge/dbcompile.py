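"""Database assembly plumbing: metadata parsing, header encoding, sharding.

Assemblies are grouped into species by the ``species_taxid`` column of an
NCBI-dialect ``assembly_summary`` table; the representative of a group is
the member whose ``refseq_category`` is "reference genome" (preferred) or
"representative genome".  Database FASTA headers encode taxonomy and genome
size in a fixed grammar so downstream profilers can recover both without a
side-channel lookup::

    >{accession}|taxid={t}|sptaxid={s}|len={bp}|lineage={rank__name;...}|org={organism}

Spaces in names become underscores and '|' is forbidden inside fields; the
grammar round-trips losslessly through :func:`decode_header`.  Records are
concatenated into shards of roughly ``target_bytes`` (default 3 GB — a
convenient size for aligner indexing) by greedy fill in input order; a
record is never split across shards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import Genome, TaxonomyRecord

__all__ = [
    "AssemblyRecord",
    "SpeciesGroup",
    "Shard",
    "parse_assembly_summary",
    "group_by_species",
    "encode_header",
    "decode_header",
    "shard_records",
    "DEFAULT_SHARD_BYTES",
]

DEFAULT_SHARD_BYTES = 3_000_000_000

#: 0-based fallback columns of the headerless NCBI assembly_summary dialect.
_POSITIONAL = {
    "assembly_accession": 0,
    "refseq_category": 4,
    "taxid": 5,
    "species_taxid": 6,
    "organism_name": 7,
    "assembly_level": 11,
}
_REQUIRED = tuple(_POSITIONAL)


@dataclass(frozen=True)
class AssemblyRecord:
    assembly_accession: str
    species_taxid: str
    taxid: str
    organism_name: str
    assembly_level: str = ""
    refseq_category: str = ""
    local_path: str = ""

    def __post_init__(self) -> None:
        if not self.assembly_accession:
            raise ValueError("assembly_accession must be non-empty")


@dataclass
class SpeciesGroup:
    species_taxid: str
    members: list[AssemblyRecord]
    representative: str | None = None


@dataclass
class Shard:
    index: int
    records: list = field(default_factory=list)
    byte_size: int = 0


def parse_assembly_summary(stream: Iterable[str]) -> list[AssemblyRecord]:
    """Parse an NCBI-style assembly_summary table.

    '#'-prefixed lines are comments; the last comment line before the data
    may carry tab-separated column names, otherwise the standard NCBI column
    positions are assumed.  A data line with too few columns raises with its
    line number; a header lacking a required column raises naming it.
    """
    columns: dict[str, int] | None = None
    records: list[AssemblyRecord] = []
    n_needed = max(_POSITIONAL.values()) + 1
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = [f.strip() for f in line.lstrip("#").strip().split("\t")]
            if "assembly_accession" in fields:
                columns = {name: i for i, name in enumerate(fields)}
                missing = [c for c in _REQUIRED if c not in columns]
                if missing:
                    raise ValueError(f"missing required column: {missing[0]}")
                n_needed = max(columns[c] for c in _REQUIRED) + 1
            continue
        cols = columns or _POSITIONAL
        parts = line.split("\t")
        if len(parts) < n_needed:
            raise ValueError(
                f"line {lineno}: expected at least {n_needed} columns, got {len(parts)}"
            )
        get = lambda name: parts[cols[name]].strip() if name in cols else ""
        records.append(
            AssemblyRecord(
                assembly_accession=get("assembly_accession"),
                species_taxid=get("species_taxid"),
                taxid=get("taxid"),
                organism_name=get("organism_name"),
                assembly_level=get("assembly_level"),
                refseq_category=get("refseq_category"),
                local_path=parts[cols["local_path"]].strip()
                if columns and "local_path" in columns and len(parts) > columns["local_path"]
                else "",
            )
        )
    return records


def group_by_species(records: list[AssemblyRecord]) -> list[SpeciesGroup]:
    """Partition records by species_taxid; pick each group's representative.

    "reference genome" wins over "representative genome"; with neither, the
    group has no designated representative.
    """
    groups: dict[str, SpeciesGroup] = {}
    for rec in records:
        group = groups.setdefault(rec.species_taxid, SpeciesGroup(rec.species_taxid, []))
        group.members.append(rec)
    for group in groups.values():
        for category in ("reference genome", "representative genome"):
            chosen = [m for m in group.members if m.refseq_category == category]
            if chosen:
                group.representative = chosen[0].assembly_accession
                break
    return list(groups.values())


def _clean_field(value: str, what: str) -> str:
    if "|" in value:
        raise ValueError(f"'|' not allowed in header field {what}: {value!r}")
    value = value.replace(" ", "_")
    if what.startswith("lineage") and "__" in value:
        # '__' is the rank/name separator of the lineage grammar
        raise ValueError(f"'__' not allowed in {what}: {value!r}")
    return value


def encode_header(genome: Genome) -> str:
    """Database FASTA header encoding taxonomy and genome size ('>' included)."""
    tax = genome.taxonomy
    lineage = ";".join(
        f"{_clean_field(rank, 'lineage rank')}__{_clean_field(name, 'lineage name')}"
        for rank, name in tax.lineage
    )
    return (
        f">{_clean_field(genome.accession, 'accession')}"
        f"|taxid={_clean_field(tax.taxid, 'taxid')}"
        f"|sptaxid={_clean_field(tax.species_taxid, 'species_taxid')}"
        f"|len={genome.total_size}"
        f"|lineage={lineage}"
        f"|org={_clean_field(tax.organism_name, 'organism_name')}"
    )


def decode_header(header: str) -> dict:
    """Inverse of :func:`encode_header`.

    Returns accession, taxid, species_taxid, total_size, lineage (tuple of
    (rank, name) pairs) and organism_name; underscores stand in for the
    original spaces and are not restored.
    """
    header = header.lstrip(">")
    accession, *rest = header.split("|")
    fields = dict(part.split("=", 1) for part in rest)
    lineage = tuple(
        tuple(item.split("__", 1))
        for item in fields.get("lineage", "").split(";")
        if item
    )
    return {
        "accession": accession,
        "taxid": fields.get("taxid", ""),
        "species_taxid": fields.get("sptaxid", ""),
        "total_size": int(fields.get("len", "0")),
        "lineage": lineage,
        "organism_name": fields.get("org", ""),
    }


def shard_records(
    records: Sequence, target_bytes: int = DEFAULT_SHARD_BYTES, size_of=None
) -> list[Shard]:
    """Greedy in-order sharding.

    A new shard starts when adding the next record would exceed
    ``target_bytes`` and the current shard is non-empty; a single oversize
    record occupies its own shard.  ``size_of`` maps a record to its byte
    size (default ``len``).
    """
    if target_bytes <= 0:
        raise ValueError("target_bytes must be positive")
    size_of = size_of or len
    shards: list[Shard] = []
    current = Shard(index=0)
    for record in records:
        nbytes = size_of(record)
        if current.records and current.byte_size + nbytes > target_bytes:
            shards.append(current)
            current = Shard(index=len(shards))
        current.records.append(record)
        current.byte_size += nbytes
    if current.records:
        shards.append(current)
    return shards


def make_taxonomy(record: AssemblyRecord, lineage: tuple = ()) -> TaxonomyRecord:
    """Taxonomy metadata derived from an assembly-summary record."""
    return TaxonomyRecord(
        taxid=record.taxid,
        species_taxid=record.species_taxid,
        lineage=tuple(lineage),
        organism_name=record.organism_name,
    )
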