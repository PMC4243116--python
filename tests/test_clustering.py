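import itertools

import numpy as np
import pytest

from apccooc import (
    degree_matrix,
    eigengap_k,
    kmedoids_cluster,
    laplacian_rw,
    mst_hierarchical_cluster,
    select_best_cluster,
    spectral_cluster,
)
from apccooc.clustering import ClusteringResult, _kmedoids_fixed_k
from tests.conftest import block_graph, graph_from_w


def random_symmetric(n, seed, density=0.7):
    rng = np.random.default_rng(seed)
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.triu(W, 1)
    W = W + W.T
    return np.clip(W, 0.0, 0.95)


class TestLaplacian:
    def test_degree_row_sums(self):
        assert np.array_equal(degree_matrix([[0, 1], [1, 0]]), np.diag([1.0, 1.0]))
        assert np.array_equal(degree_matrix(np.zeros((3, 3))), np.zeros((3, 3)))
        W = random_symmetric(7, seed=1)
        naive = np.diag([sum(W[i, j] for j in range(7)) for i in range(7)])
        assert np.allclose(degree_matrix(W), naive)

    def test_two_node_closed_form(self):
        L = laplacian_rw([[0, 1], [1, 0]])
        assert np.allclose(L, [[1, -1], [-1, 1]])
        assert np.allclose(sorted(np.linalg.eigvals(L).real), [0, 2])

    def test_row_stochastic_complement(self):
        W = random_symmetric(6, seed=2) + 0.01  # ensure positive degrees
        np.fill_diagonal(W, 0)
        L = laplacian_rw(W)
        assert np.allclose((np.eye(6) - L).sum(axis=1), 1.0, atol=1e-9)

    def test_zero_degree_vertex_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="isolate not removed"):
            laplacian_rw(W)

    @pytest.mark.parametrize("n_components", [1, 2, 3, 4])
    def test_zero_eigenvalue_multiplicity_counts_components(self, n_components):
        sizes = [3] * n_components
        g = block_graph(sizes, intra=0.8)
        eigs = np.sort(np.linalg.eigvals(laplacian_rw(g.W)).real)
        assert int((np.abs(eigs) < 1e-8).sum()) == n_components

    def test_eigenvalues_real_in_zero_two(self):
        for seed in range(5):
            W = random_symmetric(6, seed=seed) + 0.01
            np.fill_diagonal(W, 0)
            eigs = np.linalg.eigvals(laplacian_rw(W))
            assert np.abs(eigs.imag).max() < 1e-9
            assert eigs.real.min() > -1e-9 and eigs.real.max() < 2 + 1e-9

    def test_spectrum_matches_independent_eigensolver(self):
        # exhaustive over all 4-vertex weighted graphs, sampled for 5-6
        from apccooc.clustering import _eig_rw
        weights = [0.0, 0.2, 0.5, 1.0]
        count = 0
        for combo in itertools.product(weights, repeat=6):
            W = np.zeros((4, 4))
            W[np.triu_indices(4, 1)] = combo
            W = W + W.T
            if (W.sum(axis=1) == 0).any():
                continue
            mine = _eig_rw(W)[0]
            oracle = np.sort(np.linalg.eigvals(laplacian_rw(W)).real)
            assert np.allclose(mine, oracle, atol=1e-8)
            count += 1
        assert count > 1000
        rng = np.random.default_rng(3)
        for n in (5, 6):
            for _ in range(100):
                W = np.zeros((n, n))
                iu = np.triu_indices(n, 1)
                W[iu] = rng.choice([0.0, 0.2, 0.5, 1.0], size=len(iu[0]))
                W = W + W.T
                if (W.sum(axis=1) == 0).any():
                    continue
                mine = _eig_rw(W)[0]
                oracle = np.sort(np.linalg.eigvals(laplacian_rw(W)).real)
                assert np.allclose(mine, oracle, atol=1e-8)


class TestEigengap:
    def test_gap_after_second(self):
        assert eigengap_k([0, 0.01, 1.2, 1.3]) == 2

    def test_single_gap(self):
        assert eigengap_k([0, 2]) == 1

    def test_two_disconnected_cliques(self):
        g = block_graph([3, 3], intra=1.0)
        eigs = np.sort(np.linalg.eigvals(laplacian_rw(g.W)).real)
        assert eigengap_k(eigs) == 2

    def test_equal_gaps_warn_k1(self):
        with pytest.warns(UserWarning, match="eigengaps equal"):
            assert eigengap_k([0.0, 0.5, 1.0, 1.5]) == 1


def ncut(W, side):
    """Normalized cut of a bipartition (oracle)."""
    n = len(W)
    other = [i for i in range(n) if i not in side]
    cut = sum(W[i, j] for i in side for j in other)
    vol_a = sum(W[i, j] for i in side for j in range(n))
    vol_b = sum(W[i, j] for i in other for j in range(n))
    return cut / vol_a + cut / vol_b


class TestSpectral:
    def test_two_disjoint_cliques_recovered(self):
        g = block_graph([3, 3], intra=1.0)
        r = spectral_cluster(g)
        assert r.k == 2
        assert r.partition() == {frozenset(g.ids[:3]), frozenset(g.ids[3:])}

    def test_duplicated_coverage_groups_recovered(self):
        g = block_graph([2, 4], intra=1.0)
        r = spectral_cluster(g)
        assert r.partition() == {frozenset(g.ids[:2]), frozenset(g.ids[2:])}
        # larger cluster gets label 1 (size-descending relabeling)
        assert {r.assignment[v] for v in g.ids[2:]} == {1}

    def test_isolates_become_singletons(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        g = graph_from_w(W)
        r = spectral_cluster(g)
        assert r.assignment["APC1"] == r.assignment["APC2"]
        assert len({r.assignment["APC3"], r.assignment["APC4"],
                    r.assignment["APC1"]}) == 3

    def test_trivial_when_fewer_than_two_connected(self):
        g = graph_from_w(np.zeros((3, 3)))
        r = spectral_cluster(g)
        assert r.k == 3

    def test_planted_two_block_equals_min_ncut_bipartition(self):
        rng = np.random.default_rng(12)
        n = 10
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < 5) == (j < 5)
                w = rng.normal(0.9, 0.05) if same else rng.normal(0.05, 0.05)
                W[i, j] = W[j, i] = float(np.clip(w, 0.0, 1.0))
        g = graph_from_w(W)
        r = spectral_cluster(g)
        assert r.k == 2
        best_side = min(
            (set(side)
             for m in range(1, n // 2 + 1)
             for side in itertools.combinations(range(n), m)),
            key=lambda s: ncut(W, s),
        )
        want = {frozenset(g.ids[i] for i in best_side),
                frozenset(g.ids[i] for i in range(n) if i not in best_side)}
        assert r.partition() == want

    def test_first_eigenvalue_near_zero_for_connected(self):
        g = block_graph([5], intra=0.7)
        r = spectral_cluster(g)
        assert abs(r.eigenvalues[0]) < 1e-8


class TestKMedoids:
    def test_two_components_found(self):
        g = block_graph([3, 4], intra=0.9)
        r = kmedoids_cluster(g)
        assert r.k == 2
        assert r.partition() == {frozenset(g.ids[:3]), frozenset(g.ids[3:])}

    def test_medoid_maximizes_within_cluster_score(self):
        # scores: J(a,b)=0.9, J(a,c)=0.8, J(b,c)=0.2 -> medoid a (1.7)
        W = np.array([[0, 0.9, 0.8], [0.9, 0, 0.2], [0.8, 0.2, 0]])
        labels, medoids, _ = _kmedoids_fixed_k(W, 1)
        assert medoids == [0]
        assert set(labels.tolist()) == {0}

    @staticmethod
    def exhaustive_best_pair(W):
        return max(
            sum(max(W[v, m1], W[v, m2]) for v in range(len(W))
                if v not in (m1, m2))
            for m1, m2 in itertools.combinations(range(len(W)), 2)
        )

    def test_objective_matches_exhaustive_medoid_oracle(self):
        # random weights but two-component structure, the regime the
        # component-seeded initialization is designed for
        rng = np.random.default_rng(21)
        W = np.zeros((8, 8))
        for i, j in itertools.combinations(range(8), 2):
            if (i < 4) == (j < 4):
                W[i, j] = W[j, i] = 0.05 + 0.9 * rng.random()
        _, _, objective = _kmedoids_fixed_k(W, 2)
        assert objective == pytest.approx(self.exhaustive_best_pair(W))

    def test_converged_objective_never_exceeds_global_optimum(self):
        # on unstructured graphs alternating optimization may stop at a
        # local optimum, but can never beat the exhaustive one
        for seed in range(6):
            W = random_symmetric(8, seed=seed) + 0.05
            np.fill_diagonal(W, 0)
            _, _, objective = _kmedoids_fixed_k(W, 2)
            assert objective <= self.exhaustive_best_pair(W) + 1e-9

    def test_objective_not_below_initial_assignment(self):
        W = random_symmetric(9, seed=4) + 0.05
        np.fill_diagonal(W, 0)
        _, _, converged = _kmedoids_fixed_k(W, 3)
        init = [0, 1, 2]  # k > component count: farthest-first picks differ,
        # but the converged objective must beat any single fixed-medoid assignment
        start = sum(max(W[v, m] for m in init) for v in range(9) if v not in init)
        assert converged >= start - 1e-9


class TestMST:
    def test_hand_traced_cut(self):
        W = np.array([[0, 0.9, 0.8], [0.9, 0, 0.2], [0.8, 0.2, 0]])
        g = graph_from_w(W, ids=["a", "b", "c"])
        r = mst_hierarchical_cluster(g, 2)
        assert r.partition() == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_equal_weight_chain_tie_break(self):
        W = np.array([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
        g = graph_from_w(W, ids=["a", "b", "c"])
        r = mst_hierarchical_cluster(g, 2)
        # lexicographically smallest edge id (a, b) is cut first
        assert r.partition() == {frozenset({"a"}), frozenset({"b", "c"})}

    def test_tree_weight_matches_spanning_tree_enumeration(self):
        from apccooc.clustering import _max_spanning_forest
        for seed in range(4):
            W = random_symmetric(6, seed=seed, density=0.8) + 0.05
            np.fill_diagonal(W, 0)
            g = graph_from_w(W)
            forest = _max_spanning_forest(g)
            got = sum(w for _, _, w in forest)
            edges = [(i, j) for i in range(6) for j in range(i + 1, 6) if W[i, j] > 0]
            best = -1.0
            for combo in itertools.combinations(edges, 5):
                parent = list(range(6))

                def find(x):
                    while parent[x] != x:
                        x = parent[x]
                    return x

                ok = True
                for u, v in combo:
                    ru, rv = find(u), find(v)
                    if ru == rv:
                        ok = False
                        break
                    parent[ru] = rv
                if ok:
                    best = max(best, sum(W[u, v] for u, v in combo))
            assert got == pytest.approx(best)

    def test_k_out_of_reach_rejected(self):
        g = block_graph([2, 2], intra=1.0)
        with pytest.raises(ValueError, match="not achievable"):
            mst_hierarchical_cluster(g, 1)


class TestSelectBest:
    def test_lowest_average_distance_wins(self):
        emb = np.array([[0.0], [0.1], [5.0], [5.7]])
        r = ClusteringResult(
            algorithm="spectral",
            assignment={"a": 1, "b": 1, "c": 2, "d": 2},
            k=2,
            embedding=emb,
            embedding_ids=["a", "b", "c", "d"],
            avg_embedding_distance={1: 0.1, 2: 0.7},
        )
        assert select_best_cluster(r) == 1

    def test_all_singletons_is_an_error(self):
        r = ClusteringResult(
            algorithm="spectral", assignment={"a": 1, "b": 2}, k=2,
            embedding=np.zeros((2, 1)), embedding_ids=["a", "b"],
            avg_embedding_distance={},
        )
        with pytest.raises(ValueError, match="no connected cluster"):
            select_best_cluster(r)

    def test_distances_match_naive_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        g = block_graph([3, 4], intra=0.9)
        r = spectral_cluster(g)
        emb = {v: r.embedding[i] for i, v in enumerate(r.embedding_ids)}
        for label, got in r.avg_embedding_distance.items():
            members = r.members(label)
            dists = [np.linalg.norm(emb[u] - emb[v])
                     for u, v in itertools.combinations(members, 2)]
            assert got == pytest.approx(np.mean(dists))


class TestCrossAlgorithm:
    @pytest.mark.parametrize("sizes", [[3, 3], [2, 4], [3, 3, 4]])
    def test_spectral_and_kmedoids_agree_on_separable_blocks(self, sizes):
        g = block_graph(sizes, intra=0.9, inter=0.0)
        spec = spectral_cluster(g)
        kmed = kmedoids_cluster(g)
        assert spec.partition() == kmed.partition()

    @pytest.mark.parametrize("algo", ["spectral", "kmedoids", "mst"])
    def test_permutation_equivariance(self, algo):
        g = block_graph([3, 4], intra=0.85, inter=0.0)
        perm = [5, 2, 6, 0, 3, 1, 4]
        W2 = g.W[np.ix_(perm, perm)]
        ids2 = [g.ids[i] for i in perm]
        g2 = graph_from_w(W2, ids=ids2)
        if algo == "spectral":
            r1, r2 = spectral_cluster(g), spectral_cluster(g2)
        elif algo == "kmedoids":
            r1, r2 = kmedoids_cluster(g), kmedoids_cluster(g2)
        else:
            r1, r2 = mst_hierarchical_cluster(g, 2), mst_hierarchical_cluster(g2, 2)
        assert r1.partition() == r2.partition()
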