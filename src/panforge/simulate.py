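"""Conspecific strain simulation with recorded ground truth, plus brute-force oracles.

The simulator emulates a bacterial species under a star phylogeny: every
strain derives independently from one shared core sequence by point
mutations and small indels, and additionally carries a few strain- or
subset-specific accessory segments inserted at random loci.  Accessory
sequences are rejection-sampled to share no canonical 21-mer with the core,
which makes "novel content" unambiguous in tests: the true pan-genome size
is exactly ``core_len`` plus the summed lengths of the distinct accessory
segments, and every accessory segment must reappear verbatim in exactly its
carrier strains.

Everything is driven by ``numpy.random.default_rng(seed)``, so identical
parameters give byte-identical genomes and truth across runs and platforms.

The module also houses the brute-force comparators used to judge the
iterative builder: the canonical k-mer set/union oracle, and a "segmented"
pan-genome that mimics what block-wise multiple whole-genome alignment
produces (the first genome cut at every block boundary, plus every strain's
exclusive blocks, deduplicated by k-mer containment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignParams, align_pair, query_exclusive_regions
from .model import Contig, Genome, Interval, TaxonomyRecord, reverse_complement
from .pangenome import PanContig, PanGenome, ProvenanceRecord

__all__ = [
    "SimParams",
    "AccessorySegment",
    "SpeciesTruth",
    "simulate_species",
    "kmer_set",
    "kmer_union_oracle",
    "segmented_pangenome_oracle",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    Rates are per base of core sequence; ``accessory_per_strain`` and
    ``accessory_len`` are inclusive integer ranges; ``shared_accessory_prob``
    is the chance that an accessory slot reuses an existing segment (shared
    accessory content) instead of inventing a new one.
    """

    core_len: int = 200_000
    n_strains: int = 10
    snp_rate: float = 0.005
    indel_rate: float = 0.0005
    indel_max_len: int = 10
    accessory_per_strain: tuple[int, int] = (1, 3)
    accessory_len: tuple[int, int] = (2000, 10_000)
    shared_accessory_prob: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 <= self.snp_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("mutation rates must be in [0, 1)")
        if not (0 <= self.shared_accessory_prob < 1):
            raise ValueError("shared_accessory_prob must be in [0, 1)")
        if self.core_len <= 0 or self.n_strains < 1 or self.indel_max_len < 1:
            raise ValueError("lengths and counts must be positive")


@dataclass
class AccessorySegment:
    """One distinct accessory segment and where it was inserted."""

    segment_id: str
    sequence: str
    carriers: list[str]
    insertion_loci: dict[str, int]  # accession -> locus on the mutated core


@dataclass
class SpeciesTruth:
    """Simulator ground truth driving parameter-recovery tests."""

    core_sequence: str
    accessory_segments: list[AccessorySegment]
    mutation_log: dict[str, list[tuple[int, str, str]]]
    seed: int

    @property
    def true_pan_size(self) -> int:
        return len(self.core_sequence) + sum(
            len(s.sequence) for s in self.accessory_segments
        )


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate_core(
    core: np.ndarray, params: SimParams, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply SNPs then indels to a 2-bit-coded core; return sequence and log."""
    log: list[tuple[int, str, str]] = []
    seq = core.copy()
    snp_pos = np.flatnonzero(rng.random(len(seq)) < params.snp_rate)
    if snp_pos.size:
        shift = rng.integers(1, 4, size=snp_pos.size)
        old = seq[snp_pos].copy()
        seq[snp_pos] = (seq[snp_pos] + shift) % 4
        for p, o, n in zip(snp_pos, old, seq[snp_pos]):
            log.append((int(p), "snp", f"{'ACGT'[o]}>{'ACGT'[n]}"))
    indel_pos = np.flatnonzero(rng.random(len(seq)) < params.indel_rate)
    parts: list[np.ndarray] = []
    cursor = 0
    for p in indel_pos:
        p = int(p)
        if p < cursor:  # swallowed by a previous deletion
            continue
        length = int(rng.integers(1, params.indel_max_len + 1))
        if rng.random() < 0.5:
            ins = rng.integers(0, 4, size=length)
            parts.append(seq[cursor:p])
            parts.append(ins)
            cursor = p
            log.append((p, "ins", _BASES[ins].tobytes().decode("ascii")))
        else:
            parts.append(seq[cursor:p])
            cursor = min(len(seq), p + length)
            log.append((p, "del", str(cursor - p)))
    parts.append(seq[cursor:])
    out = np.concatenate(parts) if len(parts) > 1 else parts[0]
    return _BASES[out].tobytes().decode("ascii"), log


def _sample_accessory(
    rng: np.random.Generator,
    params: SimParams,
    core_kmers: set[str],
    max_tries: int = 50,
) -> str:
    """A random segment sharing no canonical 21-mer with the core."""
    length = int(rng.integers(params.accessory_len[0], params.accessory_len[1] + 1))
    for _ in range(max_tries):
        seq = _random_dna(rng, length)
        if not (kmer_set(seq, 21) & core_kmers):
            return seq
    raise RuntimeError("could not sample a core-disjoint accessory segment")


def simulate_species(params: SimParams) -> tuple[list[Genome], SpeciesTruth]:
    """Generate strain genomes and ground truth for one simulated species."""
    rng = np.random.default_rng(params.seed)
    core_codes = rng.integers(0, 4, size=params.core_len).astype(np.uint8)
    core = _BASES[core_codes].tobytes().decode("ascii")
    core_kmers = kmer_set(core, 21)

    segments: list[AccessorySegment] = []
    mutation_log: dict[str, list[tuple[int, str, str]]] = {}
    genomes: list[Genome] = []
    lo, hi = params.accessory_per_strain
    for i in range(params.n_strains):
        accession = f"SIM{i:03d}"
        mutated, log = _mutate_core(core_codes, params, rng)
        mutation_log[accession] = log

        n_acc = int(rng.integers(lo, hi + 1))
        chosen: list[AccessorySegment] = []
        for _ in range(n_acc):
            if segments and rng.random() < params.shared_accessory_prob:
                seg = segments[int(rng.integers(0, len(segments)))]
                if any(s is seg for s in chosen):
                    continue
            else:
                seg = AccessorySegment(
                    segment_id=f"acc{len(segments):03d}",
                    sequence=_sample_accessory(rng, params, core_kmers),
                    carriers=[],
                    insertion_loci={},
                )
                segments.append(seg)
            chosen.append(seg)

        loci = sorted(
            (int(p) for p in rng.integers(0, len(mutated) + 1, size=len(chosen))),
            reverse=True,
        )
        strain_seq = mutated
        for seg, locus in zip(chosen, loci):
            seg.carriers.append(accession)
            seg.insertion_loci[accession] = locus
            strain_seq = strain_seq[:locus] + seg.sequence + strain_seq[locus:]

        genomes.append(
            Genome(
                accession=accession,
                contigs=[Contig(f"{accession}_chr", strain_seq)],
                taxonomy=TaxonomyRecord(
                    taxid=str(90000 + i),
                    species_taxid="90000",
                    organism_name=f"Simulatus exemplaris {accession}",
                ),
            )
        )
    truth = SpeciesTruth(core, segments, mutation_log, params.seed)
    return genomes, truth


def kmer_set(sequence: str, k: int) -> set[str]:
    """Distinct canonical k-mers (lexicographic min of forward/revcomp).

    K-mers containing any base outside ACGT are excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: set[str] = set()
    rc_full = reverse_complement(sequence)
    n = len(sequence)
    for i in range(n - k + 1):
        fwd = sequence[i : i + k]
        rc = rc_full[n - k - i : n - i]
        canonical = fwd if fwd <= rc else rc
        out.add(canonical)
    valid = set("ACGT")
    return {kmer for kmer in out if set(kmer) <= valid}


def kmer_union_oracle(genomes: list[Genome], k: int) -> set[str]:
    """Union of canonical k-mer sets over all contigs of all genomes.

    Brute-force stand-in for the content of a species pan-genome.
    """
    union: set[str] = set()
    for genome in genomes:
        for contig in genome.contigs:
            union |= kmer_set(contig.sequence, k)
    return union


def pangenome_kmer_set(pan: PanGenome, k: int = 21) -> set[str]:
    """Canonical k-mer content of a pan-genome."""
    out: set[str] = set()
    for contig in pan.contigs:
        out |= kmer_set(contig.sequence, k)
    return out


def segmented_pangenome_oracle(
    genomes: list[Genome], params: AlignParams | None = None
) -> PanGenome:
    """Block-segmented pan-genome comparator.

    Mimics the contig structure that block-reporting multiple whole-genome
    alignment yields: every non-first genome is aligned independently to the
    first genome; the first genome is split at all block boundaries; every
    genome's exclusive blocks are added as separate contigs; finally contigs
    whose 21-mer content is >= 99% contained in earlier contigs are dropped.
    """
    if not genomes:
        raise ValueError("no genomes")
    params = params or AlignParams()
    first = genomes[0]
    # block ends within one anchor-placement margin of a contig end are not
    # genuine segmentation boundaries
    edge_tol = params.k + params.w
    cuts: dict[str, set[int]] = {c.id: set() for c in first.contigs}
    lengths = {c.id: c.length for c in first.contigs}
    exclusive: list[tuple[str, str]] = []  # (id, sequence)
    for genome in genomes[1:]:
        aln = align_pair(genome, first, params)
        for block in aln.blocks:
            cuts[block.ref_contig].update(
                p
                for p in (block.ref_interval.start, block.ref_interval.end)
                if edge_tol < p < lengths[block.ref_contig] - edge_tol
            )
        for iv in query_exclusive_regions(genome, aln, params.min_exclusive_len):
            seq = next(c.sequence for c in genome.contigs if c.id == iv.contig_id)
            exclusive.append(
                (f"{genome.accession}|{iv.contig_id}:{iv.start}-{iv.end}", seq[iv.start : iv.end])
            )

    pieces: list[tuple[str, str, ProvenanceRecord]] = []
    for contig in first.contigs:
        bounds = sorted({0, contig.length} | {p for p in cuts[contig.id] if 0 < p < contig.length})
        for s, e in zip(bounds[:-1], bounds[1:]):
            pieces.append(
                (
                    f"{first.accession}|{contig.id}:{s}-{e}",
                    contig.sequence[s:e],
                    ProvenanceRecord(first.accession, contig.id, Interval(contig.id, s, e), 0),
                )
            )
    for name, seq in exclusive:
        acc, rest = name.split("|", 1)
        cid, span = rest.rsplit(":", 1)
        s, e = (int(x) for x in span.split("-"))
        pieces.append((name, seq, ProvenanceRecord(acc, cid, Interval(cid, s, e), 1)))

    seen: set[str] = set()
    contigs: list[PanContig] = []
    for name, seq, prov in pieces:
        if not seq:
            continue
        kmers = kmer_set(seq, 21)
        if kmers and len(kmers & seen) / len(kmers) >= 0.99:
            continue
        seen |= kmers
        contigs.append(PanContig(name, seq, prov))
    species_taxid = first.taxonomy.species_taxid
    return PanGenome(species_taxid, contigs, [g.accession for g in genomes])
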