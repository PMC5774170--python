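"""Independent brute-force oracles used by the test suite.

Everything here is written naively — plain Python loops, string k-mers,
exhaustive dynamic programming — and deliberately shares no code with the
library paths it is used to check.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def naive_canonical(kmer: str) -> str:
    rc = naive_revcomp(kmer)
    return kmer if kmer <= rc else rc


def naive_kmer_set(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= set("ACGT"):
            out.add(naive_canonical(kmer))
    return out


def naive_minimizers(seq: str, k: int, w: int) -> list[tuple[int, str]]:
    """Per-window minimum canonical k-mer scan; leftmost position on ties."""
    n = len(seq) - k + 1
    if n <= 0:
        return []
    canon: list[str | None] = []
    for i in range(n):
        kmer = seq[i : i + k]
        canon.append(naive_canonical(kmer) if set(kmer) <= set("ACGT") else None)
    weff = min(w, n)
    selected: dict[int, str] = {}
    for start in range(n - weff + 1):
        window = [(canon[i], i) for i in range(start, start + weff) if canon[i] is not None]
        if window:
            kmer, pos = min(window)
            selected[pos] = kmer
    return sorted(selected.items())


def chain_oracle(anchors, max_gap: int, min_chain_span: int):
    """Exhaustive O(n^2) DP chainer; returns blocks as comparable tuples.

    Mirrors the chaining contract: maximise anchors per chain; predecessor
    ties resolve to the latest (query-sorted) compatible anchor; the best
    chain ends at the earliest maximum; chains are extracted best-first with
    full recomputation, then filtered by query span.
    """
    groups: dict[tuple[str, str], list] = {}
    for a in anchors:
        groups.setdefault((a.ref_contig, a.strand), []).append(a)
    blocks = []
    for (ref_contig, strand), grp in groups.items():
        grp = sorted(grp, key=lambda a: (a.query_pos, a.ref_pos))
        k = grp[0].k
        alive = list(range(len(grp)))
        while alive:
            score = {}
            parent = {}
            for jj, j in enumerate(alive):
                score[j] = 1
                parent[j] = None
                best, best_i = 0, None
                for i in alive[:jj]:
                    a, b = grp[i], grp[j]
                    if a.query_pos >= b.query_pos:
                        continue
                    if b.query_pos - a.query_pos - k > max_gap:
                        continue
                    if strand == "+":
                        if a.ref_pos >= b.ref_pos or b.ref_pos - a.ref_pos - k > max_gap:
                            continue
                    else:
                        if a.ref_pos <= b.ref_pos or a.ref_pos - b.ref_pos - k > max_gap:
                            continue
                    if score[i] >= best:
                        best, best_i = score[i], i
                if best_i is not None:
                    score[j] = best + 1
                    parent[j] = best_i
            end, end_score = None, 0
            for j in alive:  # earliest maximum
                if score[j] > end_score:
                    end, end_score = j, score[j]
            chain = []
            node = end
            while node is not None:
                chain.append(node)
                node = parent[node]
            chain.reverse()
            alive = [i for i in alive if i not in set(chain)]
            qs = grp[chain[0]].query_pos
            qe = grp[chain[-1]].query_pos + k
            if qe - qs < min_chain_span:
                continue
            rlo = min(grp[chain[0]].ref_pos, grp[chain[-1]].ref_pos)
            rhi = max(grp[chain[0]].ref_pos, grp[chain[-1]].ref_pos) + k
            blocks.append((qs, qe, ref_contig, rlo, rhi, strand, len(chain)))
    return sorted(blocks)
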