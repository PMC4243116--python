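"""Partitioning the co-occurrence graph into Co-occurrence Clusters.

Three algorithms operate on the Jaccard-weighted APC graph:

* spectral clustering on the random-walk Laplacian L_rw = I - D^-1 W, with
  the number of clusters chosen by the eigengap heuristic and k-means run on
  the leading eigenvector coordinates (Shi-Malik convention; rows are not
  renormalized);
* k-medoids, where each medoid is the APC maximizing the summed
  co-occurrence score to the rest of its cluster, initialized to the first
  APC of each connected component;
* hierarchical clustering by maximum spanning tree (Prim) with repeated cuts
  of the minimal-weight tree edge.

Vertices with no positive co-occurrence cannot enter D^-1; they are split
off as singleton clusters before the Laplacian is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .cooccur import CoOccurrenceGraph


# ---------------------------------------------------------------------------
# Laplacian building blocks
# ---------------------------------------------------------------------------

def degree_matrix(W: np.ndarray) -> np.ndarray:
    """Diagonal matrix of row sums d_i = sum_j W(i, j)."""
    W = np.asarray(W, dtype=float)
    return np.diag(W.sum(axis=1))


def laplacian_rw(W: np.ndarray) -> np.ndarray:
    """Random-walk Laplacian L_rw = I - D^-1 W.

    Requires every vertex to have positive degree; isolates must be split
    off first (see :func:`spectral_cluster`).
    """
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("isolate not removed: zero-degree vertex in W")
    return np.eye(len(W)) - (W / d[:, None])


def _eig_rw(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/vectors of L_rw via the symmetric normalized Laplacian.

    L_rw is similar to L_sym = I - D^-1/2 W D^-1/2; solving the symmetric
    problem keeps the spectrum real and the solver stable.  Eigenvectors are
    mapped back by D^-1/2 and returned sorted by ascending eigenvalue.
    """
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("isolate not removed: zero-degree vertex in W")
    inv_sqrt = 1.0 / np.sqrt(d)
    L_sym = np.eye(len(W)) - (inv_sqrt[:, None] * W * inv_sqrt[None, :])
    vals, U = np.linalg.eigh(L_sym)
    vecs = inv_sqrt[:, None] * U
    order = np.argsort(vals)
    return vals[order], vecs[:, order]


def eigengap_k(eigenvalues: np.ndarray, max_consider: int = 10) -> int:
    """Number of clusters = count of eigenvalues before the largest gap.

    Only the first ``max_consider`` eigenvalues are examined for stability on
    small graphs.  Ties take the smallest k; equal gaps everywhere fall back
    to k = 1 with a warning.
    """
    eigs = np.asarray(eigenvalues, dtype=float)
    if len(eigs) < 2:
        raise ValueError("need at least 2 eigenvalues")
    eigs = eigs[: min(len(eigs), max_consider)]
    gaps = np.diff(eigs)
    if np.allclose(gaps, gaps[0]):
        if len(gaps) > 1:
            warnings.warn("all eigengaps equal; defaulting to k=1")
        return 1
    return int(np.argmax(gaps)) + 1


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    """Cluster assignment plus the quantities that justify it.

    ``assignment`` maps APC id -> label in 1..k, labels ordered by cluster
    size descending.  Spectral results also carry the ascending eigenvalues,
    the eigenvector embedding of the non-isolated vertices and the average
    pairwise embedding distance per multi-member cluster.
    """

    algorithm: str
    assignment: dict[str, int]
    k: int
    eigenvalues: np.ndarray | None = None
    embedding: np.ndarray | None = None
    embedding_ids: list[str] | None = None
    avg_embedding_distance: dict[int, float] = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return [v for v, lab in self.assignment.items() if lab == label]

    def partition(self) -> set[frozenset[str]]:
        """The label-free partition, for comparisons across algorithms."""
        out: dict[int, set[str]] = {}
        for v, lab in self.assignment.items():
            out.setdefault(lab, set()).add(v)
        return {frozenset(s) for s in out.values()}


def _relabel(ids: list[str], raw: dict[str, int]) -> dict[str, int]:
    """Relabel clusters 1..k by size descending; ties by first vertex index."""
    groups: dict[int, list[int]] = {}
    for idx, v in enumerate(ids):
        groups.setdefault(raw[v], []).append(idx)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    assignment: dict[str, int] = {}
    for new_label, g in enumerate(ordered, start=1):
        for idx in g:
            assignment[ids[idx]] = new_label
    return assignment


# ---------------------------------------------------------------------------
# Spectral clustering
# ---------------------------------------------------------------------------

def spectral_cluster(g: CoOccurrenceGraph, k: int | None = None, *,
                     seed: int = 1, n_init: int = 10,
                     include_first_eigenvector: bool = True,
                     max_consider: int = 10) -> ClusteringResult:
    """Spectral clustering of the co-occurrence graph.

    Zero-degree vertices become singleton clusters.  On the remainder the
    random-walk Laplacian is eigendecomposed; k comes from the eigengap
    heuristic unless given; vertices are embedded as rows of the first k
    eigenvector columns (including the constant first one by default) and
    clustered by k-means with a fixed seed and ``n_init`` restarts.
    """
    W = g.W
    degrees = W.sum(axis=1)
    core = [i for i in range(g.n) if degrees[i] > 0]
    isolates = [i for i in range(g.n) if degrees[i] == 0]

    raw: dict[str, int] = {}
    next_label = 0
    eigenvalues = None
    embedding = None
    embedding_ids = None

    if len(core) < 2:
        for i in range(g.n):
            raw[g.ids[i]] = next_label
            next_label += 1
    else:
        Wc = W[np.ix_(core, core)]
        vals, vecs = _eig_rw(Wc)
        eigenvalues = vals
        kc = k if k is not None else eigengap_k(vals, max_consider=max_consider)
        kc = max(1, min(kc, len(core)))
        first = 0 if include_first_eigenvector else 1
        cols = vecs[:, first:first + kc]
        if cols.shape[1] == 0:
            cols = vecs[:, :1]
        embedding = cols
        embedding_ids = [g.ids[i] for i in core]
        if kc == 1:
            labels = np.zeros(len(core), dtype=int)
        else:
            km = KMeans(n_clusters=kc, n_init=n_init, random_state=seed)
            labels = km.fit_predict(cols)
        for pos, i in enumerate(core):
            raw[g.ids[i]] = int(labels[pos])
        next_label = int(labels.max()) + 1
        for i in isolates:
            raw[g.ids[i]] = next_label
            next_label += 1

    assignment = _relabel(g.ids, raw)
    result = ClusteringResult(
        algorithm="spectral",
        assignment=assignment,
        k=max(assignment.values()),
        eigenvalues=eigenvalues,
        embedding=embedding,
        embedding_ids=embedding_ids,
    )
    if embedding is not None:
        pos_of = {v: i for i, v in enumerate(embedding_ids)}
        for label in range(1, result.k + 1):
            rows = [pos_of[v] for v in result.members(label) if v in pos_of]
            if len(rows) >= 2:
                result.avg_embedding_distance[label] = float(
                    pdist(embedding[rows]).mean()
                )
    return result


def select_best_cluster(r: ClusteringResult) -> int:
    """The most connected cluster: lowest average embedding distance.

    Considers only clusters with at least two embedded members; singleton
    clusters (including split-off isolates) are excluded.
    """
    if r.embedding is None or r.embedding_ids is None:
        raise ValueError("select_best_cluster needs a spectral result with embedding")
    if not r.avg_embedding_distance:
        raise ValueError("no connected cluster: every cluster is a singleton")
    return min(r.avg_embedding_distance.items(), key=lambda kv: (kv[1], kv[0]))[0]


# ---------------------------------------------------------------------------
# k-medoids
# ---------------------------------------------------------------------------

def _components(W: np.ndarray) -> list[list[int]]:
    """Connected components of the positive-edge graph, ordered and sorted
    by their smallest vertex index."""
    n_comp, labels = connected_components((W > 0).astype(int), directed=False)
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(i)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


def _kmedoids_fixed_k(W: np.ndarray, k: int) -> tuple[np.ndarray, list[int], float]:
    """Alternating k-medoids for a given k; fully deterministic.

    Medoids start as the first vertex of each connected component; extra
    medoids (k larger than the component count) are added farthest-first
    (lowest maximum similarity to the existing medoids, ties to the smallest
    index).  Assignment sends each vertex to the medoid with the highest
    co-occurrence score; the update step picks the member maximizing the
    summed score to the rest of its cluster.
    """
    n = len(W)
    comps = _components(W)
    medoids = [c[0] for c in comps][:k]
    while len(medoids) < k:
        candidates = [v for v in range(n) if v not in medoids]
        v_best = min(candidates, key=lambda v: (max(W[v, m] for m in medoids), v))
        medoids.append(v_best)
    medoids = sorted(medoids)

    labels = np.zeros(n, dtype=int)
    for _ in range(200):
        for v in range(n):
            if v in medoids:
                labels[v] = medoids.index(v)
            else:
                sims = [W[v, m] for m in medoids]
                labels[v] = int(np.argmax(sims))
        new_medoids = []
        for ci in range(len(medoids)):
            members = [v for v in range(n) if labels[v] == ci]
            best = max(members, key=lambda v: (sum(W[v, u] for u in members), -v))
            new_medoids.append(best)
        new_medoids = sorted(new_medoids)
        if new_medoids == medoids:
            break
        medoids = new_medoids
    objective = float(sum(W[v, medoids[labels[v]]] for v in range(n)
                          if v not in medoids))
    return labels, medoids, objective


def _dunn_index(D: np.ndarray, labels: np.ndarray) -> float:
    inter = np.inf
    intra = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                intra = max(intra, D[i, j])
            else:
                inter = min(inter, D[i, j])
    if not np.isfinite(inter):
        return 0.0
    if intra == 0.0:
        return np.inf if inter > 0 else 0.0
    return inter / intra


def _classical_mds(D: np.ndarray) -> np.ndarray:
    """Torgerson embedding of a distance matrix (positive eigenvalue dims)."""
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    keep = vals > 1e-10
    if not keep.any():
        return np.zeros((n, 1))
    return vecs[:, keep] * np.sqrt(vals[keep])


def _within_between_ratio(W: np.ndarray, labels: np.ndarray) -> float:
    within, between = [], []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(W[i, j])
    if not within:
        return 0.0
    if not between:
        return np.inf
    mb = float(np.mean(between))
    return np.inf if mb == 0 else float(np.mean(within)) / mb


def _select_k_by_indices(W: np.ndarray, k_range: list[int]) -> int:
    """Majority vote of five internal validity indices; ties to smaller k.

    Indices: silhouette (precomputed 1 - W distances), Calinski-Harabasz and
    Davies-Bouldin on a classical-MDS embedding of the distances, the Dunn
    index, and the within/between mean-similarity ratio.
    """
    n = len(W)
    D = 1.0 - W
    np.fill_diagonal(D, 0.0)
    coords = _classical_mds(D)
    scores: dict[str, dict[int, float]] = {name: {} for name in
                                           ("sil", "ch", "db", "dunn", "ratio")}
    for k in k_range:
        labels, _, _ = _kmedoids_fixed_k(W, k)
        if len(set(labels.tolist())) != k:
            continue
        if 2 <= k <= n - 1:
            try:
                scores["sil"][k] = silhouette_score(D, labels, metric="precomputed")
            except ValueError:
                pass
            try:
                scores["ch"][k] = calinski_harabasz_score(coords, labels)
                scores["db"][k] = davies_bouldin_score(coords, labels)
            except ValueError:
                pass
        scores["dunn"][k] = _dunn_index(D, labels)
        scores["ratio"][k] = _within_between_ratio(W, labels)
    votes: list[int] = []
    orientation = {"sil": 1, "ch": 1, "db": -1, "dunn": 1, "ratio": 1}
    for name, table in scores.items():
        if not table:
            continue
        sign = orientation[name]
        best = min(table.items(), key=lambda kv: (-sign * kv[1], kv[0]))[0]
        votes.append(best)
    if not votes:
        return min(k_range)
    counts: dict[int, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    return min(k for k, c in counts.items() if c == max(counts.values()))


def kmedoids_cluster(g: CoOccurrenceGraph, k: int | None = None) -> ClusteringResult:
    """k-medoids on the co-occurrence graph (similarity maximization).

    With k unspecified, candidate k values from the component count up to
    |V| are compared by five internal validity indices (majority vote, ties
    to smaller k).
    """
    W = g.W
    comps = _components(W)
    c = len(comps)
    if k is None:
        k_range = list(range(c, g.n + 1))
        k = _select_k_by_indices(W, k_range) if len(k_range) > 1 else c
    if not 1 <= k <= g.n:
        raise ValueError("k out of range")
    if k < c:
        raise ValueError(f"k={k} below the component count {c}")
    labels, _, _ = _kmedoids_fixed_k(W, k)
    raw = {g.ids[i]: int(labels[i]) for i in range(g.n)}
    assignment = _relabel(g.ids, raw)
    return ClusteringResult(algorithm="kmedoids", assignment=assignment,
                            k=max(assignment.values()))


def kmedoids_objective(g: CoOccurrenceGraph, k: int) -> float:
    """Converged k-medoids objective: summed score of members to their medoid."""
    _, _, objective = _kmedoids_fixed_k(g.W, k)
    return objective


# ---------------------------------------------------------------------------
# Maximum-spanning-tree hierarchical clustering
# ---------------------------------------------------------------------------

def _max_spanning_forest(g: CoOccurrenceGraph) -> list[tuple[int, int, float]]:
    """Prim's maximum spanning tree per component; deterministic tie-breaks
    by the lexicographic (sorted) id pair of the edge."""
    W = g.W
    edges: list[tuple[int, int, float]] = []
    for comp in _components(W):
        in_tree = {comp[0]}
        remaining = set(comp) - in_tree
        while remaining:
            best = None
            for u in in_tree:
                for v in remaining:
                    if W[u, v] > 0:
                        eid = tuple(sorted((g.ids[u], g.ids[v])))
                        key = (W[u, v], _neg_pair(eid))
                        if best is None or key > best[0]:
                            best = (key, u, v)
            if best is None:
                break  # component of isolates (no positive edges)
            _, u, v = best
            edges.append((u, v, float(W[u, v])))
            in_tree.add(v)
            remaining.discard(v)
    return edges


class _neg_pair(tuple):
    """Tuple ordered in reverse, so the lexicographically smallest id pair
    wins inside a max()."""

    def __lt__(self, other):
        return tuple.__gt__(self, other)

    def __gt__(self, other):
        return tuple.__lt__(self, other)


def mst_hierarchical_cluster(g: CoOccurrenceGraph, k: int) -> ClusteringResult:
    """Cut the maximum spanning tree at its weakest edges into k clusters.

    The forest starts with one tree per connected component; each removal of
    the currently minimal-weight tree edge (ties: lexicographic edge id)
    raises the cluster count by one.
    """
    if g.n < 2:
        raise ValueError("need at least 2 vertices")
    if not 1 <= k <= g.n:
        raise ValueError("k out of range")
    edges = _max_spanning_forest(g)
    start_clusters = g.n - len(edges)
    if k < start_clusters:
        raise ValueError(
            f"k={k} not achievable: graph already has {start_clusters} components"
        )
    edges = sorted(edges, key=lambda e: (e[2], tuple(sorted((g.ids[e[0]], g.ids[e[1]])))))
    n_cut = k - start_clusters
    kept = edges[n_cut:]

    parent = list(range(g.n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v, _ in kept:
        parent[find(u)] = find(v)
    raw = {g.ids[i]: find(i) for i in range(g.n)}
    assignment = _relabel(g.ids, raw)
    return ClusteringResult(algorithm="mst", assignment=assignment,
                            k=max(assignment.values()))
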