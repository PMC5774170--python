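# Methods

## Iterative pan-genome construction

The pan-genome of a species is built by traversing its strain genomes once.
The designated representative genome (or, without one, the largest
assembly) seeds the reference; every further strain, taken in descending
assembly size (ties broken lexicographically by accession so builds are
reproducible), is aligned to the current reference and only its
query-exclusive regions — maximal intervals covered by no alignment block
on either strand — are appended as new contigs. The reference is never
trimmed, edited or reordered, which gives three properties the package
tests as invariants: monotone growth of total size, byte-identical prefix
preservation across iterations, and verbatim appearance of every appended
region in its source strain. It also makes incremental updating trivial:
one alignment of the new strain against the standing pan-genome.

Species with many sequenced strains are capped before building: the
representative plus the 49 largest strains by default, the representative
plus the 19 largest under the fungal preset (`FUNGAL_MAX_STRAINS`). The
short-contig filter (drop contigs with length < 1000 bp; the boundary
length 1000 survives, reading "shorter than" literally) runs once, after
the final iteration, because it is a database-condensing step rather than
part of the alignment loop.

### Appended-region flanks

Block boundaries are anchor-defined, so the uncovered interval around a
novel insertion begins a few bases inside the flanking shared sequence
rather than exactly at the junction. If the exclusive interval alone were
appended, the k-mers spanning the junction between shared and novel
sequence would exist in no pan-genome contig. Each appended region is
therefore padded with `flank` bp (default 25, chosen ≥ 21 − 1 so that all
junction 21-mers are retained) of aligned context on each side. The
provenance record stores the padded interval, so appended contigs remain
verbatim substrings of their source strain; the cost is a few tens of
duplicated bases per appended contig, negligible against the 2% size
tolerance the recovery tests use. A consequence is that an appended contig
for an isolated novel segment of length L has length ≈ L + 2·flank plus up
to ~2k of anchor slack; tests size their tolerances as 2k + 2·flank.

## The alignment engine

Production database pipelines typically delegate block finding to an
external whole-genome aligner; here the aligner is built in, exposing the
same contract (collinear blocks between query and reference), so the
toolkit is self-contained and testable at desk scale.

Anchoring uses canonical minimizers: each k-mer (default k = 15; values
below 11 are rejected as unspecific at genome scale) is encoded 2-bit,
compared with its reverse complement, and the lexicographic minimum per
window of w = 10 consecutive k-mers is selected (leftmost on ties; k-mers
containing non-ACGT bases never anchor). Expected anchor density is
~2/(w+1) per bp, dense enough that conspecific strains (> 95% identity)
anchor every few bases. Matching canonical codes between query and
reference minimizers yield exact anchors with strand orientation.

Chaining maximises anchors per chain under collinearity (query positions
strictly increasing; reference positions increasing on '+', decreasing on
'−') with query- and reference-gap each ≤ `max_gap` (default 1000 bp, large
enough to bridge SNP/indel-induced anchor deserts in conspecific strains,
small enough that unrelated regions do not join). Because a predecessor
must lie within `max_gap` on the query axis, the DP inspects only a sliding
window of the query-sorted anchors — near-linear in practice — and is
exactly equivalent to the exhaustive O(n²) chainer the test suite uses as
an oracle, with fully specified tie-breaks (nearest predecessor on score
ties; earliest chain end; best-first extraction with recomputation). Chains
spanning < `min_chain_span` (100 bp) are dropped, which also discards the
occasional single spurious 15-mer anchor between unrelated sequences.
Exclusive regions shorter than `min_exclusive_len` (100 bp) are not
reported: sub-block indel slack is not novel content. No base-level
extension beyond anchors is attempted; tolerances of ~2k bp account for
this wherever exact boundaries matter. Genomes are treated as linear; there
are no wraparound anchors across circular origins.

## Exogenous-sequence detection

Marker genes are searched against every pan-genome contig with exact
15-mer seeds (minimizer-sampled on the marker, both strands) clustered by
diagonal into candidate windows, followed by local Smith–Waterman
(match +1, mismatch −2, gap open 2, extend 1) over each window.
Significance uses the Karlin–Altschul statistic E = K·m·n·e^(−λS) with
λ = 1.33 and K = 0.621 (standard ungapped nucleotide values for this
scoring), m the marker length and n the contig length. Hits are kept at
identity ≥ 0.9 and E ≤ 1e−6 (both adjustable). Per contig, hits are
aggregated with distinct-marker counting — repeat hits to one marker count
once — and per-marker coverage is computed after merging that marker's
aligned intervals on the marker axis, so a split alignment is not
double-counted but also not under-counted; the best-single-hit alternative
would be more conservative and can be recovered by inspecting the hits
table. A contig is flagged when it hits ≥ 2 distinct markers or when one
marker's merged coverage exceeds 50%; single sub-50% hits are reported as
"fragmentary" since they plausibly reflect true homology of shared gene
motifs.

## Database compilation

`assembly_summary` parsing accepts the NCBI dialect with either a named
'#'-header or the standard column positions, reports malformed lines by
line number, and treats an optional `local_path` column as the location of
the already-downloaded FASTA (network retrieval is out of scope). Species
grouping partitions by `species_taxid`; "reference genome" beats
"representative genome" when picking a group's representative. Headers
follow the grammar
`>{acc}|taxid=..|sptaxid=..|len=..|lineage=rank__name;..|org=..` with
spaces replaced by underscores, '|' forbidden in fields and '__' reserved
as the lineage separator; the decoder inverts everything except the
space/underscore substitution. Sharding fills files greedily in input
order toward a byte target (default 3·10⁹ ≈ the ~2.8 GB convenient for
aligner indexing), never splits a record, and gives an oversize record its
own shard.

## The simulator and what it does (not) show

`simulate_species` emulates one species under a star phylogeny: every
strain derives independently from the same core sequence (no tree
structure, no recombination), with per-base SNPs (default 0.005 — about
99.5% average nucleotide identity, typical conspecific divergence), small
indels (rate 0.0005, lengths 1–10), and 1–3 accessory segments of 2–10 kb
per strain, 20% of which reuse an existing segment so some accessory
content is shared between strains. Accessory sequences are
rejection-sampled to share no canonical 21-mer with the core, making "novel
content" sharp: the true pan-genome size is exactly core length plus
distinct accessory lengths, and recovery can be asserted as exact substring
search. All randomness flows from one `numpy` PRNG seed recorded in the
truth object, so outputs are byte-identical across runs and platforms.

What passing these tests shows: the builder recovers known novel content
within 2% of truth, never rearranges what it has built, and matches
brute-force k-mer oracles on mutation-free input. What it does not show:
behaviour under rearrangement/inversion (not simulated), realistic
phylogenetic structure, read-level artefacts, or contamination patterns of
real assemblies.

Two structural observations the measurements make explicit:

- **Per-strain variant k-mers are discarded by design.** The pan-genome
  keeps one representative copy of every aligned region, so SNP variants of
  covered regions in later strains do not enter the database. A strain
  21-mer survives only if its window carries neither a strain-private nor a
  seed-strain mutation, i.e. an expected fraction ≈ (1−µ)^{2·21} ≈ 0.81 of
  core k-mers at µ = 0.005. Measured per-strain 21-mer recall against the
  pan-genome is accordingly ~0.80–0.85 (1.0 for the seed strain) — this is
  the redundancy compression the method exists for, not a defect; recall
  approaches 1 as µ → 0.
- **Chimeric junction k-mers of shared segments.** When a later strain
  carries an accessory segment the pan-genome already contains, but at a
  different insertion locus, the k-mers spanning *its* junction are unique
  to that strain yet fully covered (core on one side, known segment on the
  other, gap ≪ `min_exclusive_len`), so they are absent from the
  pan-genome. This bounds the k-mer Jaccard against the union oracle
  slightly below 1 (typically 0.9985–0.9998 depending on how many shared
  segments the simulation draws).

The segmented comparator (`segmented_pangenome_oracle`) reproduces what
block-reporting multiple alignment leaves behind — the first genome cut at
every block boundary plus every strain's exclusive blocks, deduplicated at
99% 21-mer containment; block ends within k + w of a contig end are not
treated as cuts, as they are anchor-placement artefacts. On the default
simulation its mean contig length is several-fold below the iterative
builder's, which is the fragmentation contrast the iterative algorithm is
designed to avoid.

## Diversity statistics

Shannon's H = −Σ pᵢ ln pᵢ (natural log; 0·ln 0 := 0, zero-abundance
species excluded from s) and Pielou's J = H / ln s, undefined for s = 1.
Computation delegates to `scipy.stats.entropy`; the tests pin
hand-evaluated values (H([½,¼,¼]) ≈ 1.039721, J ≈ 0.946395) and the exact
J = 1 of uniform vectors.

## Problem sizes

The default test and acceptance workloads use a 200 kb core with 10
strains (~320 kb true pan-genome), which exercises every code path —
multi-kilobase insertions, shared segments, SNP/indel anchor deserts,
incremental updates — while a full build plus all oracle comparisons
completes in about a minute on one CPU. Unit tests use a 20 kb core.
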