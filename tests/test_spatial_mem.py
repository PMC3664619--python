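import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from betaspace.core_data import SiteTable
from betaspace.spatial_mem import (GRAPH_TYPES, NeighbourGraph, WeightScheme,
                                   aicc, build_graph, mem_eigenvectors,
                                   morans_i, select_eigenvectors,
                                   select_mem_model, weight_matrix)

from conftest import random_incidence, random_sites


def brute_force_edges(pts, kind):
    """Independent O(n^3) edge-criterion check for RNG and Gabriel graphs."""
    D = squareform(pdist(pts))
    n = len(pts)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            ok = True
            for k in range(n):
                if k in (i, j):
                    continue
                if kind == "rng" and max(D[i, k], D[j, k]) < D[i, j]:
                    ok = False
                    break
                if kind == "gabriel" and D[i, k] ** 2 + D[j, k] ** 2 < D[i, j] ** 2:
                    ok = False
                    break
            if ok:
                edges.add((i, j))
    return edges


class TestGraphs:
    def test_unit_square_mst_has_three_edges(self, square_sites):
        assert len(build_graph(square_sites, "mst").edges) == 3

    def test_unit_square_gabriel_sides_not_diagonals(self, square_sites):
        edges = build_graph(square_sites, "gabriel").edge_set()
        assert edges == {(0, 1), (1, 2), (2, 3), (0, 3)}

    def test_nesting_hierarchy_random_points(self):
        for seed in range(20):
            st = random_sites(12, seed=seed)
            e = {g: build_graph(st, g).edge_set() for g in GRAPH_TYPES}
            assert e["mst"] <= e["rng"] <= e["gabriel"] <= e["delaunay"]

    def test_rng_gabriel_match_brute_force(self):
        st = random_sites(15, seed=3)
        pts = st.coords()
        assert build_graph(st, "rng").edge_set() == brute_force_edges(pts, "rng")
        assert build_graph(st, "gabriel").edge_set() == brute_force_edges(pts, "gabriel")

    def test_collinear_delaunay_suggests_jitter(self):
        st = SiteTable(["a", "b", "c", "d"], np.arange(4.0), np.zeros(4) + 0.0)
        with pytest.raises(ValueError, match="jitter"):
            build_graph(st, "delaunay")


class TestWeights:
    def test_binary_equals_adjacency(self, square_sites):
        g = build_graph(square_sites, "gabriel")
        np.testing.assert_array_equal(weight_matrix(g, WeightScheme("binary")),
                                      g.adjacency())

    def test_f2_longest_edge_zero(self, square_sites):
        g = build_graph(square_sites, "delaunay")
        W = weight_matrix(g, WeightScheme("f2"))
        lengths = {(i, j): d for i, j, d in g.edges}
        (i, j), dmax = max(lengths.items(), key=lambda kv: kv[1])
        assert W[i, j] == 0.0

    def test_f1_path_weights(self):
        g = NeighbourGraph(3, [(0, 1, 1.0), (1, 2, 2.0)], "mst")
        W = weight_matrix(g, WeightScheme("f1"))
        assert W[0, 1] == 1.0 and W[1, 2] == 0.5

    def test_f1_zero_length_edge_rejected(self):
        g = NeighbourGraph(3, [(0, 1, 0.0), (1, 2, 2.0)], "mst")
        with pytest.raises(ValueError, match="positive edge lengths"):
            weight_matrix(g, WeightScheme("f1"))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            WeightScheme("f3")


class TestMemBasis:
    def test_zero_weights_empty_basis(self):
        basis = mem_eigenvectors(np.zeros((6, 6)))
        assert basis.k == 0

    def test_centering_orthogonality_order(self):
        st = random_sites(20, seed=5)
        W = weight_matrix(build_graph(st, "gabriel"), WeightScheme("f1"))
        basis = mem_eigenvectors(W)
        V = basis.eigenvectors
        np.testing.assert_allclose(V.sum(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(V.T @ V, np.eye(basis.k), atol=1e-8)
        assert np.all(np.diff(basis.eigenvalues) <= 1e-12)

    def test_chain_first_eigenvector_monotone(self):
        # 4 sites on a line, binary chain weights
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1.0
        basis = mem_eigenvectors(W)
        v1 = basis.eigenvectors[:, 0]
        assert np.all(np.diff(v1) > 0) or np.all(np.diff(v1) < 0)

    def test_morans_i_positive_and_ranked_with_eigenvalues(self):
        st = random_sites(18, seed=6)
        W = weight_matrix(build_graph(st, "rng"), WeightScheme("binary"))
        basis = mem_eigenvectors(W)
        I = np.array([morans_i(basis.eigenvectors[:, k], W) for k in range(basis.k)])
        assert np.all(I > 0)
        assert np.all(np.diff(I) <= 1e-10)  # same order as eigenvalues


class TestSelection:
    def test_aicc_guard(self):
        with pytest.raises(ValueError):
            aicc(1.0, n=5, p=4)

    def test_exact_planted_recovery(self):
        st = random_sites(26, seed=7)
        W = weight_matrix(build_graph(st, "gabriel"), WeightScheme("binary"))
        basis = mem_eigenvectors(W)
        y = 2 * basis.eigenvectors[:, 1] - basis.eigenvectors[:, 3]
        retained, _, _ = select_eigenvectors(y, basis)
        assert sorted(retained) == [1, 3]

    def test_twelve_candidates_evaluated(self):
        st = random_sites(15, seed=8)
        inc = random_incidence(15, 20, seed=8)
        from betaspace.beta_partition import beta_matrices
        bt = beta_matrices(inc)
        bt.beta_repl.labels = st.site_ids  # align labels
        sel = select_mem_model(
            type(bt.beta_repl)(st.site_ids, bt.beta_repl.values), st)
        assert len(sel.all_candidates) == 12
        assert sel.aicc <= min(c["aicc"] for c in sel.all_candidates)

    def test_alignment_required(self):
        st = random_sites(10, seed=9)
        inc = random_incidence(10, 12, seed=9)
        from betaspace.beta_partition import beta_matrices
        beta = beta_matrices(inc).beta_repl
        beta.labels = list(reversed(st.site_ids))
        with pytest.raises(ValueError, match="aligned"):
            select_mem_model(beta, st)

    def test_path_is_nested_and_best_is_minimum(self):
        st = random_sites(22, seed=10)
        W = weight_matrix(build_graph(st, "delaunay"), WeightScheme("f2"))
        basis = mem_eigenvectors(W)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(22)
        retained, best, path = select_eigenvectors(y, basis)
        sizes = [len(rec["indices"]) for rec in path]
        assert sizes == list(range(len(path)))  # strictly nested, one at a time
        assert best <= min(rec["aicc"] for rec in path) + 0.01
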