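import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panforge import (
    AlignParams,
    Anchor,
    Contig,
    Genome,
    align_pair,
    chain_anchors,
    covered_query_length,
    find_anchors,
    index_reference,
    query_exclusive_regions,
    reverse_complement,
)
from panforge.alignment import minimizers

from _oracles import chain_oracle, naive_minimizers
from conftest import random_dna


def one_contig_genome(seq: str, accession: str = "G", contig: str = "c1") -> Genome:
    return Genome(accession=accession, contigs=[Contig(contig, seq)])


class TestIndexReference:
    def test_homopolymer_collapses_to_single_kmer(self):
        idx = index_reference(one_contig_genome("A" * 100), k=15, w=10)
        assert idx.n_distinct_kmers == 1

    def test_n_in_every_window_yields_empty_index(self):
        seq = ("ACGTACGTACGTAC" + "N") * 7  # N every 15 bp: no valid 15-mer
        idx = index_reference(one_contig_genome(seq), k=15, w=10)
        assert idx.n_distinct_kmers == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            index_reference(one_contig_genome(""), k=15, w=10)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            index_reference(one_contig_genome("ACGT" * 100), k=9, w=10)

    def test_matches_brute_force_minimizer_scan(self, rng):
        seq = random_dna(rng, 10_000)
        expected = naive_minimizers(seq, 15, 10)
        got = minimizers(seq, 15, 10)
        assert [p for p, _, _ in got] == [p for p, _ in expected]
        assert len({c for _, c, _ in got}) == len({kmer for _, kmer in expected})
        idx = index_reference(one_contig_genome(seq), k=15, w=10)
        assert idx.n_distinct_kmers == len({kmer for _, kmer in expected})

    @given(st.integers(0, 2**32 - 1))
    def test_minimizer_scan_equals_oracle_on_random_sequences(self, seed):
        local = np.random.default_rng(seed)
        seq = random_dna(local, local.integers(0, 400))
        # sprinkle some N runs
        if len(seq) > 50:
            pos = int(local.integers(0, len(seq) - 5))
            seq = seq[:pos] + "N" * int(local.integers(1, 5)) + seq[pos + 5 :]
        got = [(p, c) for p, c, _ in minimizers(seq, 11, 4)]
        expected = naive_minimizers(seq, 11, 4)
        assert [p for p, _ in got] == [p for p, _ in expected]


class TestFindAnchors:
    def test_identity_anchors_forward(self, rng):
        seq = random_dna(rng, 5000)
        ref = one_contig_genome(seq, "R", "rc")
        idx = index_reference(ref, 15, 10)
        anchors = find_anchors(Contig("q", seq), idx)
        assert anchors and all(a.strand == "+" for a in anchors)
        assert len(anchors) == len(minimizers(seq, 15, 10))

    def test_reverse_complement_query_flips_strand(self, rng):
        seq = random_dna(rng, 5000)
        idx = index_reference(one_contig_genome(seq), 15, 10)
        fwd = find_anchors(Contig("q", seq), idx)
        rev = find_anchors(Contig("q", reverse_complement(seq)), idx)
        assert len(rev) == len(fwd)
        assert all(a.strand == "-" for a in rev)

    def test_unrelated_sequences_share_no_anchors(self, rng):
        idx = index_reference(one_contig_genome(random_dna(rng, 3000)), 15, 10)
        assert find_anchors(Contig("q", random_dna(rng, 3000)), idx) == []

    def test_anchor_soundness_exact_match(self, rng):
        """Every anchor's query k-mer equals the (rev-comp'd) reference k-mer."""
        ref_seq = random_dna(rng, 4000)
        query_seq = ref_seq[500:2500] + random_dna(rng, 500)
        idx = index_reference(one_contig_genome(ref_seq, contig="rc"), 15, 10)
        anchors = find_anchors(Contig("q", query_seq), idx)
        assert anchors
        for a in anchors:
            q_kmer = query_seq[a.query_pos : a.query_pos + a.k]
            r_kmer = ref_seq[a.ref_pos : a.ref_pos + a.k]
            assert q_kmer == (r_kmer if a.strand == "+" else reverse_complement(r_kmer))


def make_anchors(pairs, strand="+", k=15, ref_contig="rc"):
    return [Anchor(q, ref_contig, r, k, strand) for q, r in pairs]


class TestChainAnchors:
    def test_perfect_diagonal_single_block(self):
        blocks = chain_anchors(make_anchors([(0, 0), (100, 100), (200, 200)]),
                               max_gap=1000, min_chain_span=100)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.query_interval.start, b.query_interval.end) == (0, 215)
        assert (b.ref_interval.start, b.ref_interval.end) == (0, 215)
        assert b.anchor_count == 3

    def test_gap_limit_splits_and_span_filter_drops(self):
        blocks = chain_anchors(make_anchors([(0, 0), (100, 100), (200, 200)]),
                               max_gap=50, min_chain_span=16)
        assert blocks == []

    def test_minus_strand_chain_requires_descending_ref(self):
        blocks = chain_anchors(make_anchors([(0, 200), (100, 100), (200, 0)], strand="-"),
                               max_gap=1000, min_chain_span=100)
        assert len(blocks) == 1
        assert blocks[0].strand == "-"
        assert blocks[0].anchor_count == 3

    @given(st.integers(0, 2**32 - 1), st.sampled_from([50, 200, 1000]),
           st.sampled_from([16, 100]))
    def test_chains_equal_exhaustive_dp_oracle(self, seed, max_gap, min_span):
        """Windowed chaining DP reproduces a naive O(n^2) chainer exactly."""
        local = np.random.default_rng(seed)
        n = int(local.integers(1, 120))
        anchors = []
        for _ in range(n):
            anchors.append(
                Anchor(
                    query_pos=int(local.integers(0, 2000)),
                    ref_contig=str(local.choice(["r1", "r2"])),
                    ref_pos=int(local.integers(0, 2000)),
                    k=15,
                    strand=str(local.choice(["+", "-"])),
                )
            )
        got = sorted(
            (
                b.query_interval.start,
                b.query_interval.end,
                b.ref_contig,
                b.ref_interval.start,
                b.ref_interval.end,
                b.strand,
                b.anchor_count,
            )
            for b in chain_anchors(anchors, max_gap, min_span)
        )
        assert got == chain_oracle(anchors, max_gap, min_span)


class TestAlignPair:
    def test_identity_alignment_covers_query(self, rng):
        seq = random_dna(rng, 50_000)
        genome = one_contig_genome(seq)
        aln = align_pair(genome, genome, AlignParams())
        assert covered_query_length(aln) >= 0.99 * len(seq)
        assert max(len(b.query_interval) for b in aln.blocks) >= 0.99 * len(seq)

    def test_insertion_leaves_uncovered_gap(self, rng):
        k = AlignParams().k
        core = random_dna(rng, 50_000)
        insert = random_dna(rng, 5000)
        query = one_contig_genome(core[:25_000] + insert + core[25_000:], "Q", "qc")
        aln = align_pair(query, one_contig_genome(core, "R", "rc"), AlignParams())
        regions = query_exclusive_regions(query, aln, 100)
        assert len(regions) == 1
        assert abs(len(regions[0]) - 5000) <= 2 * k

    def test_unrelated_genomes_produce_no_blocks(self, rng):
        a = one_contig_genome(random_dna(rng, 20_000), "A")
        b = one_contig_genome(random_dna(rng, 20_000), "B")
        assert align_pair(a, b, AlignParams()).blocks == []

    def test_empty_query_rejected(self, rng):
        ref = one_contig_genome(random_dna(rng, 2000))
        with pytest.raises(ValueError, match="empty query"):
            align_pair(one_contig_genome(""), ref, AlignParams())

    def test_strand_symmetry_of_covered_length(self, rng):
        ref_seq = random_dna(rng, 30_000)
        query_seq = ref_seq[:12_000] + random_dna(rng, 3000) + ref_seq[18_000:]
        ref = one_contig_genome(ref_seq, "R", "rc")
        params = AlignParams()
        fwd = align_pair(one_contig_genome(query_seq, "Q", "q"), ref, params)
        rev = align_pair(
            one_contig_genome(reverse_complement(query_seq), "Q", "q"), ref, params
        )
        assert covered_query_length(fwd) == covered_query_length(rev)


class TestQueryExclusiveRegions:
    def test_identity_has_no_exclusive_regions(self, rng):
        seq = random_dna(rng, 20_000)
        genome = one_contig_genome(seq)
        aln = align_pair(genome, genome, AlignParams())
        assert query_exclusive_regions(genome, aln, 100) == []

    def test_zero_block_alignment_returns_full_contigs(self, rng):
        query = one_contig_genome(random_dna(rng, 10_000), "Q", "qc")
        ref = one_contig_genome(random_dna(rng, 10_000), "R", "rc")
        aln = align_pair(query, ref, AlignParams())
        regions = query_exclusive_regions(query, aln, 100)
        assert [(r.contig_id, r.start, r.end) for r in regions] == [("qc", 0, 10_000)]

    def test_coverage_complement_partitions_query(self, rng):
        """Block cover, exclusive regions and sub-threshold gaps tile the query."""
        core = random_dna(rng, 30_000)
        query_seq = core[:10_000] + random_dna(rng, 2000) + core[14_000:]
        query = one_contig_genome(query_seq, "Q", "qc")
        aln = align_pair(query, one_contig_genome(core, "R", "rc"), AlignParams())
        min_ex = 100
        covered = np.zeros(len(query_seq), dtype=bool)
        for b in aln.blocks:
            covered[b.query_interval.start : b.query_interval.end] = True
        exclusive = np.zeros_like(covered)
        for r in query_exclusive_regions(query, aln, min_ex):
            assert not covered[r.start : r.end].any()
            exclusive[r.start : r.end] = True
        # remaining gaps must each be shorter than the reporting threshold
        rest = ~(covered | exclusive)
        gaps, run = [], 0
        for uncovered in rest:
            if uncovered:
                run += 1
            elif run:
                gaps.append(run)
                run = 0
        if run:
            gaps.append(run)
        assert all(g < min_ex for g in gaps)
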