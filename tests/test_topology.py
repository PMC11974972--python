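"""Thresholding, nodal graph metrics and AUC summaries."""

import math

import numpy as np
import pytest

from msnbiotyper.topology import (
    BinaryGraph,
    ModulePartition,
    ThresholdGrid,
    auc_over_sparsity,
    binarize_at_sparsity,
    compute_hubness,
    degree_centrality,
    detect_modules,
    nodal_efficiency,
    participation_coefficient,
)
from conftest import random_similarity


def brute_force_ne(A: np.ndarray) -> np.ndarray:
    """All-pairs BFS reference for nodal efficiency."""
    R = len(A)
    out = np.zeros(R)
    for i in range(R):
        dist = {i: 0}
        frontier = [i]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(A[u]):
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        out[i] = sum(1.0 / dv for v, dv in dist.items() if v != i) / (R - 1)
    return out


def brute_force_pc(A: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Exhaustive per-module edge sums reference for participation coefficient."""
    R = len(A)
    out = np.zeros(R)
    for i in range(R):
        k = A[i].sum()
        if k == 0:
            continue
        s = 0.0
        for m in np.unique(assignment):
            k_im = A[i][assignment == m].sum()
            s += (k_im / k) ** 2
        out[i] = 1.0 - s
    return out


class TestBinarize:
    def test_edge_count_floor_formula_over_default_grid(self, rng):
        W = random_similarity(rng, 40)
        for s in ThresholdGrid().sparsities:
            G = binarize_at_sparsity(W, s)
            assert G.n_edges == math.floor(s * 40 * 39 / 2)

    def test_r90_point_one_keeps_400_edges(self, rng):
        G = binarize_at_sparsity(random_similarity(rng, 90), 0.10)
        assert G.n_edges == 400  # floor(0.10 * 4005)

    def test_top_weights_survive(self, rng):
        W = random_similarity(rng, 5)
        G = binarize_at_sparsity(W, 0.3)  # floor(0.3*10)=3 edges
        ii, jj = np.triu_indices(5, k=1)
        kept = W[ii, jj][G.adjacency[ii, jj]]
        dropped = W[ii, jj][~G.adjacency[ii, jj]]
        assert G.n_edges == 3
        assert kept.min() >= dropped.max()

    def test_tie_break_is_deterministic(self):
        W = np.ones((6, 6))
        a = binarize_at_sparsity(W, 0.2).adjacency
        b = binarize_at_sparsity(W, 0.2).adjacency
        assert np.array_equal(a, b)

    def test_zero_edge_sparsity_rejected(self):
        with pytest.raises(ValueError):
            binarize_at_sparsity(np.ones((3, 3)), 0.1)


class TestNodalMetrics:
    def test_complete_graph(self):
        A = ~np.eye(4, dtype=bool)
        G = BinaryGraph(A, 0.5)
        assert np.array_equal(degree_centrality(G), [3, 3, 3, 3])
        np.testing.assert_allclose(nodal_efficiency(G), 1.0)

    def test_path_graph_hand_values(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        G = BinaryGraph(A, 0.5)
        assert np.array_equal(degree_centrality(G), [1, 2, 1])
        np.testing.assert_allclose(nodal_efficiency(G), [0.75, 1.0, 0.75])

    def test_isolated_node_efficiency_zero(self):
        A = np.zeros((4, 4), dtype=bool)
        A[0, 1] = A[1, 0] = True
        ne = nodal_efficiency(BinaryGraph(A, 0.1))
        assert ne[2] == 0.0 and ne[3] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(size=(15, 15)) < 0.25
        A = np.triu(A, 1)
        A = A | A.T
        G = BinaryGraph(A, 0.25)
        assert np.array_equal(degree_centrality(G), A.sum(axis=1))
        np.testing.assert_allclose(nodal_efficiency(G), brute_force_ne(A), atol=1e-12)
        part = detect_modules(G)
        np.testing.assert_allclose(
            participation_coefficient(G, part),
            brute_force_pc(A, part.assignment),
            atol=1e-12,
        )

    def test_ne_bounded_by_one(self, rng):
        A = rng.uniform(size=(20, 20)) < 0.3
        A = np.triu(A, 1)
        A = A | A.T
        ne = nodal_efficiency(BinaryGraph(A, 0.3))
        assert np.all(ne <= 1.0 + 1e-12)
        full = np.flatnonzero(A.sum(axis=1) == 19)
        np.testing.assert_allclose(ne[full], 1.0)


class TestParticipation:
    def test_all_edges_own_module_gives_zero(self):
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=bool)
        part = ModulePartition(np.array([0, 0, 0]), 0.0)
        np.testing.assert_allclose(
            participation_coefficient(BinaryGraph(A, 0.5), part), 0.0
        )

    def test_even_two_way_split_is_half(self):
        # node 0 has one edge into module 0 (node 1) and one into module 1 (node 2)
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=bool)
        part = ModulePartition(np.array([0, 0, 1]), 0.0)
        assert participation_coefficient(BinaryGraph(A, 0.5), part)[0] == pytest.approx(0.5)

    def test_two_one_one_split_hand_value(self):
        # node 0: 4 edges split 2/1/1 over modules -> 1-(.25+.0625+.0625)=0.625
        A = np.zeros((5, 5), dtype=bool)
        A[0, 1:] = A[1:, 0] = True
        part = ModulePartition(np.array([0, 0, 0, 1, 2]), 0.0)
        assert participation_coefficient(BinaryGraph(A, 0.5), part)[0] == pytest.approx(0.625)

    def test_pc_upper_bound_given_modules(self, rng):
        A = rng.uniform(size=(12, 12)) < 0.4
        A = np.triu(A, 1)
        A = A | A.T
        G = BinaryGraph(A, 0.4)
        part = detect_modules(G)
        M = part.assignment.max() + 1
        pc = participation_coefficient(G, part)
        assert np.all(pc <= 1 - 1 / M + 1e-12)


class TestModules:
    def test_two_disjoint_cliques_recovered(self):
        A = np.zeros((8, 8), dtype=bool)
        A[:4, :4] = ~np.eye(4, dtype=bool)
        A[4:, 4:] = ~np.eye(4, dtype=bool)
        part = detect_modules(BinaryGraph(A, 0.4))
        assert len(np.unique(part.assignment)) == 2
        assert len(np.unique(part.assignment[:4])) == 1
        assert len(np.unique(part.assignment[4:])) == 1

    def test_edgeless_graph_single_community(self):
        part = detect_modules(BinaryGraph(np.zeros((5, 5), dtype=bool), 0.1))
        assert np.array_equal(part.assignment, np.zeros(5))


class TestAuc:
    def test_constant_curve_rectangle(self):
        grid = ThresholdGrid()
        assert auc_over_sparsity(np.ones(len(grid)), grid) == pytest.approx(0.24)

    def test_linear_curve_triangle(self):
        grid = ThresholdGrid()
        curve = np.linspace(0, 1, len(grid))
        assert auc_over_sparsity(curve, grid) == pytest.approx(0.12)

    def test_zero_curve(self):
        grid = ThresholdGrid()
        assert auc_over_sparsity(np.zeros(len(grid)), grid) == 0.0

    def test_linearity(self, rng):
        grid = ThresholdGrid()
        a, b = rng.uniform(size=(2, len(grid)))
        assert auc_over_sparsity(a + 2 * b, grid) == pytest.approx(
            auc_over_sparsity(a, grid) + 2 * auc_over_sparsity(b, grid)
        )

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            auc_over_sparsity(np.ones(3), ThresholdGrid())


class TestComputeHubness:
    def test_deterministic_on_repeat(self, rng):
        W = random_similarity(rng, 12)
        a = compute_hubness(W).values
        b = compute_hubness(W).values
        np.testing.assert_array_equal(a, b)

    def test_matches_straightforward_reference(self, rng):
        """Independent re-implementation: loop over thresholds calling the
        brute-force metric oracles, trapezoid by hand."""
        W = random_similarity(rng, 10)
        grid = ThresholdGrid()
        ref = np.zeros((len(grid), 10, 3))
        for t, s in enumerate(grid.sparsities):
            G = binarize_at_sparsity(W, s)
            A = G.adjacency
            part = detect_modules(G)
            ref[t, :, 0] = A.sum(axis=1)
            ref[t, :, 1] = brute_force_ne(A)
            ref[t, :, 2] = brute_force_pc(A, part.assignment)
        expected = np.trapezoid(ref, grid.sparsities, axis=0)
        got = compute_hubness(W, grid).values[0]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_bridge_node_has_higher_pc(self):
        # two dense blocks joined by node 0
        rng = np.random.default_rng(5)
        R = 11
        W = rng.uniform(0.01, 0.2, size=(R, R))
        W[1:6, 1:6] += 0.7
        W[6:, 6:] += 0.7
        W[0, 1:6] = W[1:6, 0] = 0.85
        W[0, 6:] = W[6:, 0] = 0.85
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        prof = compute_hubness(W, ThresholdGrid(np.arange(0.2, 0.35, 0.01)))
        pc = prof.values[0, :, 2]
        assert pc[0] > pc[1:].mean()
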