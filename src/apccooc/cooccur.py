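"""Jaccard co-occurrence graph over APCs.

Two conserved regions that keep appearing on the same sequences are likely to
act together; the Jaccard index of their covered-sequence sets quantifies
this.  The symmetric matrix W of pairwise scores is the adjacency matrix of
the co-occurrence graph handed to the clustering algorithms.  The diagonal is
zero (no self-loops), so vertex degrees count neighbours only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .apc import AlignedPatternCluster


def jaccard(c1: AlignedPatternCluster, c2: AlignedPatternCluster) -> float:
    """|Cseq1 & Cseq2| / |Cseq1 | Cseq2|, with the 0/0 convention -> 0."""
    s1, s2 = c1.covered_sequences, c2.covered_sequences
    union = s1 | s2
    if not union:
        warnings.warn("both coverage sets empty; Jaccard defined as 0")
        return 0.0
    return len(s1 & s2) / len(union)


@dataclass
class CoOccurrenceGraph:
    """APC vertices with symmetric Jaccard edge weights.

    ``ids`` fixes the vertex order; ``W[i, j]`` is the co-occurrence score of
    vertices i and j and ``union_size[i, j]`` the size of the union of their
    coverage sets (the secondary ranking key).
    """

    ids: list[str]
    W: np.ndarray
    union_size: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise ValueError("W must be |V| x |V|")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if (self.W < 0).any() or (self.W > 1).any():
            raise ValueError("scores must lie in [0, 1]")
        if np.diag(self.W).any():
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, apc_id: str) -> int:
        return self.ids.index(apc_id)


def build_graph(apcs: list[AlignedPatternCluster],
                edge_min: float = 0.0) -> CoOccurrenceGraph:
    """All-pairs Jaccard matrix over the given APCs (vertex order = input order).

    ``edge_min`` optionally zeroes edges strictly below the threshold to
    sparsify the graph before clustering; by default every positive edge is
    kept.
    """
    if len(apcs) < 2:
        raise ValueError("nothing to cluster: need at least 2 APCs")
    n = len(apcs)
    W = np.zeros((n, n))
    union = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            score = jaccard(apcs[i], apcs[j])
            if score < edge_min:
                score = 0.0
            W[i, j] = W[j, i] = score
            u = len(apcs[i].covered_sequences | apcs[j].covered_sequences)
            union[i, j] = union[j, i] = u
    return CoOccurrenceGraph(ids=[c.id for c in apcs], W=W, union_size=union)


def rank_pairs(g: CoOccurrenceGraph) -> list[tuple[str, str, float, int]]:
    """All unordered APC pairs ranked for reporting.

    Primary key: co-occurrence score descending.  Ties: union size descending
    (the pair covering more sequences ranks higher), then lexicographic id
    pair.  The order is total and deterministic.
    """
    pairs = []
    for i in range(g.n):
        for j in range(i + 1, g.n):
            a, b = sorted((g.ids[i], g.ids[j]))
            pairs.append((a, b, float(g.W[i, j]), int(g.union_size[i, j])))
    pairs.sort(key=lambda t: (-t[2], -t[3], t[0], t[1]))
    return pairs
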