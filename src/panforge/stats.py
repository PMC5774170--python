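"""Community diversity statistics over relative-abundance vectors.

Shannon's diversity index (natural log)::

    H = -sum_i p_i * ln(p_i)        0 * ln 0 := 0

and Pielou's evenness, the Shannon index normalised by its maximum
``H_max = ln(s)`` over the ``s`` species with non-zero abundance::

    J = H / ln(s)

J is 1 exactly for a perfectly even community and tends to 0 as one species
dominates; it is undefined for a single species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy

__all__ = ["AbundanceVector", "shannon_index", "pielou_evenness"]


@dataclass
class AbundanceVector:
    """Relative abundances summing to 1; ``s`` counts non-zero species."""

    labels: list[str]
    p: np.ndarray

    def __init__(self, labels, p):
        p = np.asarray(p, dtype=float)
        if len(labels) != len(p):
            raise ValueError("labels and abundances differ in length")
        if (p < 0).any():
            raise ValueError("abundances must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {p.sum()!r})")
        if not (p > 0).any():
            raise ValueError("at least one species must have non-zero abundance")
        self.labels = list(labels)
        self.p = p

    @classmethod
    def from_counts(cls, labels, counts) -> "AbundanceVector":
        counts = np.asarray(counts, dtype=float)
        return cls(labels, counts / counts.sum())

    @property
    def s(self) -> int:
        return int((self.p > 0).sum())


def shannon_index(v: AbundanceVector) -> float:
    """Shannon diversity H in nats; zero-abundance terms contribute 0."""
    return float(entropy(v.p[v.p > 0]))


def pielou_evenness(v: AbundanceVector) -> float:
    """Pielou's evenness J = H / ln(s); requires s >= 2."""
    if v.s < 2:
        raise ValueError("evenness undefined for a single species")
    return shannon_index(v) / math.log(v.s)
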