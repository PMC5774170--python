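"""Pairwise whole-genome alignment by minimizer anchoring and collinear chaining.

The aligner finds exact-match anchors between a query genome and a reference
using canonical minimizers (lexicographically smallest of a k-mer and its
reverse complement, sampled one per window of ``w`` consecutive k-mers), then
chains co-strand, collinear anchors whose query- and reference-gaps are both
bounded by ``max_gap`` into alignment blocks.  Blocks are the only product
downstream code consumes: the pan-genome builder asks which query regions are
*not* covered by any block.

Chains are grown by dynamic programming that maximises the number of anchors
per chain; chains are extracted best-first until every anchor is consumed,
and chains whose query span falls below ``min_chain_span`` are discarded.
Because a predecessor must lie within ``max_gap`` on the query axis, the DP
only inspects a sliding window of the (query-sorted) anchor list, which keeps
the common near-identity case close to linear time.

Anchors are exact by construction: k-mers containing any non-ACGT base never
enter the index.  Block boundaries are anchor-defined — no base-level
extension is attempted — so up to roughly ``k + w`` bp of true homology can
leak into the uncovered regions flanking a block.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .model import Contig, Genome, Interval

__all__ = [
    "AlignParams",
    "Anchor",
    "AnchorIndex",
    "AlignmentBlock",
    "PairwiseAlignment",
    "index_reference",
    "find_anchors",
    "chain_anchors",
    "align_pair",
    "query_exclusive_regions",
    "covered_query_length",
]

_BASE_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class AlignParams:
    """Tunable aligner parameters.

    k: anchor k-mer size (>= 11 so random matches are rare at genome scale)
    w: minimizer window, in k-mers; anchor density is ~2/(w+1) per bp
    max_gap: maximum query/reference gap (bp) bridged within one chain
    min_chain_span: minimum query span (bp) for a chain to become a block
    min_exclusive_len: minimum length (bp) of a reported query-exclusive region
    """

    k: int = 15
    w: int = 10
    max_gap: int = 1000
    min_chain_span: int = 100
    min_exclusive_len: int = 100

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("anchor k-mer size must be >= 11")
        for name in ("w", "max_gap", "min_chain_span", "min_exclusive_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Anchor:
    """An exact k-mer match between query and reference.

    ``query_pos``/``ref_pos`` are 0-based positions of the k-mer on the
    forward strand of each sequence.  ``strand`` is '-' when the query k-mer
    matches the reverse complement of the reference k-mer.
    """

    query_pos: int
    ref_contig: str
    ref_pos: int
    k: int
    strand: str


@dataclass(frozen=True)
class AlignmentBlock:
    """A chained, collinear alignable region between query and reference."""

    query_interval: Interval
    ref_contig: str
    ref_interval: Interval
    strand: str
    anchor_count: int

    def __post_init__(self) -> None:
        if self.anchor_count < 1:
            raise ValueError("anchor_count must be >= 1")


@dataclass
class PairwiseAlignment:
    """All blocks between one query genome and the standing reference."""

    query_accession: str
    blocks: list[AlignmentBlock]
    params: AlignParams


@dataclass
class AnchorIndex:
    """Lookup from canonical minimizer codes to reference locations.

    Each entry maps an integer k-mer code to a list of
    ``(contig_id, position, forward_is_canonical)`` tuples.
    """

    k: int
    w: int
    reference_accession: str
    contig_lengths: dict[str, int]
    lookup: dict[int, list[tuple[str, int, bool]]] = field(default_factory=dict)

    @property
    def n_distinct_kmers(self) -> int:
        return len(self.lookup)


def _encode(sequence: str) -> np.ndarray:
    """Map bases to 2-bit codes; anything outside ACGT becomes -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def minimizers(sequence: str, k: int, w: int) -> list[tuple[int, int, bool]]:
    """Canonical minimizers of a sequence.

    Returns ``(position, canonical_code, forward_is_canonical)`` tuples, one
    per distinct selected position, in increasing position order.  Within each
    window of ``w`` consecutive k-mers the lexicographically smallest valid
    canonical k-mer is selected (leftmost on ties).  K-mers containing a
    non-ACGT base are never selected.
    """
    n = len(sequence) - k + 1
    if n <= 0:
        return []
    codes = _encode(sequence)
    win = sliding_window_view(codes, k).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rc = (3 - win) @ powers[::-1]
    valid = (win >= 0).all(axis=1)
    canon = np.minimum(fwd, rc)
    is_fwd = fwd <= rc
    sentinel = np.int64(4) ** k
    canon[~valid] = sentinel

    weff = min(w, n)
    windows = sliding_window_view(canon, weff)
    picked = windows.argmin(axis=1) + np.arange(n - weff + 1)
    sel = np.unique(picked)
    sel = sel[canon[sel] < sentinel]
    return [(int(p), int(canon[p]), bool(is_fwd[p])) for p in sel]


def index_reference(reference: Genome, k: int, w: int) -> AnchorIndex:
    """Build the minimizer index of a reference genome."""
    if reference is None or not reference.contigs or reference.total_size == 0:
        raise ValueError("empty reference")
    if k < 11:
        raise ValueError("anchor k-mer size must be >= 11")
    if w <= 0:
        raise ValueError("minimizer window must be positive")
    index = AnchorIndex(
        k=k,
        w=w,
        reference_accession=reference.accession,
        contig_lengths={c.id: c.length for c in reference.contigs},
    )
    for contig in reference.contigs:
        for pos, code, fwd in minimizers(contig.sequence, k, w):
            index.lookup.setdefault(code, []).append((contig.id, pos, fwd))
    return index


def find_anchors(query_contig: Contig, index: AnchorIndex) -> list[Anchor]:
    """Exact minimizer matches between one query contig and the reference."""
    anchors: list[Anchor] = []
    for qpos, code, qfwd in minimizers(query_contig.sequence, index.k, index.w):
        hits = index.lookup.get(code)
        if not hits:
            continue
        for ref_contig, rpos, rfwd in hits:
            strand = "+" if qfwd == rfwd else "-"
            anchors.append(Anchor(qpos, ref_contig, rpos, index.k, strand))
    return anchors


def _chain_group(
    q: np.ndarray,
    r: np.ndarray,
    strand: str,
    k: int,
    max_gap: int,
) -> list[list[int]]:
    """Best-first chain extraction on one (ref contig, strand) anchor group.

    Anchors must be pre-sorted by (query_pos, ref_pos).  Returns chains as
    lists of indices into the sorted arrays, in extraction order.  A chain
    maximises anchor count; the predecessor of an anchor is the compatible
    anchor with the highest chain score, breaking ties toward the nearest
    (largest-index) predecessor; the best chain ends at the lowest-index
    maximum.  After each extraction the DP is recomputed on the remainder.
    """
    chains: list[list[int]] = []
    remaining = np.arange(len(q))
    minus = strand == "-"
    while remaining.size:
        qq = q[remaining]
        rr = r[remaining]
        m = remaining.size
        score = np.ones(m, dtype=np.int64)
        parent = np.full(m, -1, dtype=np.int64)
        lo = 0
        for j in range(1, m):
            while qq[j] - qq[lo] > max_gap + k:
                lo += 1
            if lo == j:
                continue
            qi = qq[lo:j]
            ri = rr[lo:j]
            if minus:
                ok = (qi < qq[j]) & (ri > rr[j]) & (ri - rr[j] - k <= max_gap)
            else:
                ok = (qi < qq[j]) & (ri < rr[j]) & (rr[j] - ri - k <= max_gap)
            if ok.any():
                fi = score[lo:j][ok]
                best = fi.max()
                cand = np.flatnonzero(ok)[fi == best]
                parent[j] = lo + cand[-1]
                score[j] = best + 1
        end = int(np.argmax(score))  # first occurrence: lowest index on ties
        chain: list[int] = []
        node = end
        while node != -1:
            chain.append(node)
            node = int(parent[node])
        chain.reverse()
        chains.append([int(remaining[i]) for i in chain])
        remaining = np.delete(remaining, chain)
    return chains


def chain_anchors(
    anchors: list[Anchor],
    max_gap: int,
    min_chain_span: int,
    query_contig_id: str = "query",
) -> list[AlignmentBlock]:
    """Chain anchors from one (query contig, reference) pair into blocks.

    Co-strand anchors on the same reference contig are chained when collinear
    (strictly increasing query position; reference position increasing on '+',
    decreasing on '-') with query- and reference-gaps each at most
    ``max_gap``.  Chains whose query span is below ``min_chain_span`` are
    dropped; every anchor belongs to at most one chain.
    """
    if not anchors:
        return []
    groups: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.ref_contig, a.strand)].append(a)
    blocks: list[AlignmentBlock] = []
    for (ref_contig, strand) in sorted(groups):
        grp = sorted(groups[(ref_contig, strand)], key=lambda a: (a.query_pos, a.ref_pos))
        k = grp[0].k
        q = np.array([a.query_pos for a in grp], dtype=np.int64)
        r = np.array([a.ref_pos for a in grp], dtype=np.int64)
        for chain in _chain_group(q, r, strand, k, max_gap):
            qs = int(q[chain[0]])
            qe = int(q[chain[-1]]) + k
            if qe - qs < min_chain_span:
                continue
            rlo = int(min(r[chain[0]], r[chain[-1]]))
            rhi = int(max(r[chain[0]], r[chain[-1]])) + k
            blocks.append(
                AlignmentBlock(
                    query_interval=Interval(query_contig_id, qs, qe),
                    ref_contig=ref_contig,
                    ref_interval=Interval(ref_contig, rlo, rhi),
                    strand=strand,
                    anchor_count=len(chain),
                )
            )
    blocks.sort(key=lambda b: (b.query_interval.start, b.query_interval.end))
    return blocks


def align_pair(query: Genome, reference: Genome, params: AlignParams) -> PairwiseAlignment:
    """Align a query genome to the reference: index, anchor, chain.

    Both strands are searched (canonical minimizers make the anchor lookup
    strand-insensitive); blocks from all query contigs are pooled.
    """
    if query is None or not query.contigs or query.total_size == 0:
        raise ValueError("empty query")
    index = index_reference(reference, params.k, params.w)
    blocks: list[AlignmentBlock] = []
    for contig in query.contigs:
        anchors = find_anchors(contig, index)
        blocks.extend(
            chain_anchors(anchors, params.max_gap, params.min_chain_span, contig.id)
        )
    return PairwiseAlignment(query.accession, blocks, params)


def _merged_coverage(blocks: list[AlignmentBlock], contig_id: str) -> list[tuple[int, int]]:
    ivs = sorted(
        (b.query_interval.start, b.query_interval.end)
        for b in blocks
        if b.query_interval.contig_id == contig_id
    )
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def query_exclusive_regions(
    query: Genome, aln: PairwiseAlignment, min_exclusive_len: int
) -> list[Interval]:
    """Maximal query intervals covered by no block, of length >= ``min_exclusive_len``.

    Both strands count as covering.  Intervals are disjoint and sorted by
    (contig order, start).
    """
    regions: list[Interval] = []
    for contig in query.contigs:
        pos = 0
        for s, e in _merged_coverage(aln.blocks, contig.id) + [(contig.length, contig.length)]:
            if s - pos >= min_exclusive_len:
                regions.append(Interval(contig.id, pos, s))
            pos = max(pos, e)
    return regions


def covered_query_length(aln: PairwiseAlignment) -> int:
    """Total query bases covered by at least one block (either strand)."""
    contigs = {b.query_interval.contig_id for b in aln.blocks}
    return sum(
        e - s for cid in contigs for s, e in _merged_coverage(aln.blocks, cid)
    )
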