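"""Detection of exogenous sequence in pan-genome contigs via marker genes.

Genome assemblies in public archives can carry sequence from another
species, through contamination or lateral transfer.  The detector searches a
set of species-specific marker genes against every pan-genome contig with a
seeded local alignment (exact 15-mer seeds clustered by diagonal, then
Smith-Waterman over the candidate window) and keeps hits passing identity
and E-value thresholds.  A contig is flagged as potentially exogenous when
it matches at least ``min_markers`` distinct marker genes, or when the
merged aligned region of a single marker covers more than ``min_cov`` of
that marker's length.  A single sub-threshold-coverage hit is reported as
"fragmentary" — it may reflect true homology of a shared gene motif rather
than exogenous sequence.

Alignment significance uses the Karlin-Altschul statistic
``E = K * m * n * exp(-lambda * S)`` with nucleotide scoring +1/-2 and gap
open/extend 2/1 (lambda = 1.33, K = 0.621), where ``m`` is the marker
length, ``n`` the contig length and ``S`` the raw local alignment score.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .alignment import minimizers
from .model import Interval, reverse_complement
from .pangenome import PanGenome

__all__ = [
    "MarkerGene",
    "MarkerHit",
    "ContigFlag",
    "search_markers",
    "flag_contigs",
]

KARLIN_LAMBDA = 1.33
KARLIN_K = 0.621
SEED_K = 15
SEED_W = 5
_DIAG_BAND = 64  # seeds within this diagonal distance cluster together

_NT_MATRIX = balign.SubstitutionMatrix(
    bseq.NucleotideSequence.alphabet_unamb,
    bseq.NucleotideSequence.alphabet_unamb,
    np.where(np.eye(4, dtype=bool), 1, -2).astype(np.int32),
)


@dataclass(frozen=True)
class MarkerGene:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"marker {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MarkerHit:
    """One significant local alignment of a marker gene on a contig."""

    marker_id: str
    contig_id: str
    identity: float
    evalue: float
    marker_coverage: float
    contig_interval: Interval
    marker_interval: Interval
    marker_length: int = 0
    strand: str = "+"


@dataclass(frozen=True)
class ContigFlag:
    """Per-contig flagging decision.

    ``reason`` is ``multi_marker``, ``high_coverage`` or ``both`` for flagged
    contigs, and ``fragmentary`` for contigs with hits that do not meet
    either rule.
    """

    contig_id: str
    n_markers_hit: int
    max_marker_coverage: float
    flagged: bool
    reason: str


def karlin_altschul_evalue(score: int, m: int, n: int) -> float:
    """E-value of a local alignment score for search space m x n."""
    return KARLIN_K * m * n * math.exp(-KARLIN_LAMBDA * score)


def _seed_positions(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        index[sequence[i : i + k]].append(i)
    return index


def _candidate_windows(
    marker_len: int, seeds: list[tuple[int, int]], contig_len: int
) -> list[tuple[int, int]]:
    """Cluster (marker_pos, contig_pos) seeds by diagonal into contig windows."""
    pad = marker_len + 50
    by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    clusters: list[list[tuple[int, int]]] = []
    for seed in by_diag:
        diag = seed[1] - seed[0]
        if clusters and abs((clusters[-1][-1][1] - clusters[-1][-1][0]) - diag) <= _DIAG_BAND:
            clusters[-1].append(seed)
        else:
            clusters.append([seed])
    windows = []
    for cluster in clusters:
        lo = min(c for _, c in cluster)
        hi = max(c for _, c in cluster) + SEED_K
        windows.append((max(0, lo - pad), min(contig_len, hi + pad)))
    windows.sort()
    merged: list[tuple[int, int]] = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _align_window(
    marker: MarkerGene,
    window_seq: str,
    window_start: int,
    strand: str,
    contig_id: str,
    contig_len: int,
) -> MarkerHit | None:
    mseq = bseq.NucleotideSequence(marker.sequence)
    wseq = bseq.NucleotideSequence(window_seq)
    alignments = balign.align_optimal(
        mseq, wseq, _NT_MATRIX, gap_penalty=(-2, -1), local=True, max_number=1
    )
    if not alignments:
        return None
    aln = alignments[0]
    if aln.trace.shape[0] == 0 or aln.score <= 0:
        return None
    identity = balign.get_sequence_identity(aln, mode="all")
    m0, w0 = (int(x) for x in np.min(np.where(aln.trace >= 0, aln.trace, np.iinfo(np.int64).max), axis=0))
    m1, w1 = (int(x) for x in np.max(aln.trace, axis=0) + 1)
    wlen = len(window_seq)
    if strand == "-":
        # window was reverse-complemented before alignment; map back
        contig_lo = window_start + (wlen - w1)
        contig_hi = window_start + (wlen - w0)
    else:
        contig_lo = window_start + w0
        contig_hi = window_start + w1
    return MarkerHit(
        marker_id=marker.id,
        contig_id=contig_id,
        identity=float(identity),
        evalue=karlin_altschul_evalue(int(aln.score), marker.length, contig_len),
        marker_coverage=(m1 - m0) / marker.length,
        contig_interval=Interval(contig_id, contig_lo, contig_hi),
        marker_interval=Interval(marker.id, m0, m1),
        marker_length=marker.length,
        strand=strand,
    )


def search_markers(
    markers: list[MarkerGene],
    pan: PanGenome,
    min_identity: float = 0.9,
    max_evalue: float = 1e-6,
) -> list[MarkerHit]:
    """Seeded local search of every marker against every pan-genome contig.

    Returns hits with identity >= ``min_identity`` and E-value <=
    ``max_evalue``; ``marker_coverage`` is the aligned fraction of the marker
    (query) side.
    """
    if not markers:
        raise ValueError("no marker genes supplied")
    hits: list[MarkerHit] = []
    for contig in pan.contigs:
        contig_index = _seed_positions(contig.sequence, SEED_K)
        for marker in markers:
            for strand in "+-":
                mseq = marker.sequence if strand == "+" else reverse_complement(marker.sequence)
                seeds = [
                    (mpos, cpos)
                    for mpos, code, _ in minimizers(mseq, SEED_K, SEED_W)
                    for cpos in contig_index.get(mseq[mpos : mpos + SEED_K], ())
                ]
                if not seeds:
                    continue
                for wstart, wend in _candidate_windows(marker.length, seeds, contig.length):
                    window = contig.sequence[wstart:wend]
                    if strand == "-":
                        window = reverse_complement(window)
                    hit = _align_window(
                        marker, window, wstart, strand, contig.id, contig.length
                    )
                    if (
                        hit is not None
                        and hit.identity >= min_identity
                        and hit.evalue <= max_evalue
                    ):
                        hits.append(hit)
    return hits


def _merged_marker_coverage(marker_hits: list[MarkerHit]) -> float:
    """Coverage of one marker by its hits, merged on the marker axis."""
    ivs = sorted((h.marker_interval.start, h.marker_interval.end) for h in marker_hits)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    marker_len = marker_hits[0].marker_length
    if marker_len <= 0:
        return max(h.marker_coverage for h in marker_hits)
    return covered / marker_len


def flag_contigs(
    hits: list[MarkerHit],
    min_markers: int = 2,
    min_cov: float = 0.5,
) -> list[ContigFlag]:
    """Aggregate hits per contig and apply the two-tier flagging rule.

    A contig is flagged when it hits at least ``min_markers`` *distinct*
    markers (repeat hits to one marker count once), or when one marker's
    merged coverage exceeds ``min_cov``.  Contigs with hits meeting neither
    rule are reported unflagged with reason ``fragmentary``.
    """
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    per_contig: dict[str, dict[str, list[MarkerHit]]] = defaultdict(lambda: defaultdict(list))
    for hit in hits:
        per_contig[hit.contig_id][hit.marker_id].append(hit)
    flags: list[ContigFlag] = []
    for contig_id in sorted(per_contig):
        by_marker = per_contig[contig_id]
        n_markers = len(by_marker)
        max_cov = max(_merged_marker_coverage(v) for v in by_marker.values())
        multi = n_markers >= min_markers
        high = max_cov > min_cov
        if multi and high:
            reason = "both"
        elif multi:
            reason = "multi_marker"
        elif high:
            reason = "high_coverage"
        else:
            reason = "fragmentary"
        flags.append(
            ContigFlag(
                contig_id=contig_id,
                n_markers_hit=n_markers,
                max_marker_coverage=max_cov,
                flagged=multi or high,
                reason=reason,
            )
        )
    return flags
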