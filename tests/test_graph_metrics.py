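"""Small-world metrics against closed forms, brute force, and networkx."""

import numpy as np
import networkx as nx
import pytest

from motornet import (
    BinaryNetwork,
    ZMatrix,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    metric_auc,
    normalized_small_world,
    proportional_threshold,
    random_reference,
    subject_profile,
    threshold_sweep,
    transitivity,
)
from motornet.graph_metrics import (
    characteristic_path_length,
    shortest_paths,
    small_world_metrics,
)

from . import oracles


def _net(adj, threshold=0.5):
    return BinaryNetwork(adjacency=np.asarray(adj, dtype=np.uint8), threshold=threshold)


def _from_edges(n, edges):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return adj


TRIANGLE = _from_edges(3, [(0, 1), (1, 2), (0, 2)])
P3 = _from_edges(3, [(0, 1), (1, 2)])
K4_MINUS_EDGE = _from_edges(4, [(0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
STAR4 = _from_edges(4, [(0, 1), (0, 2), (0, 3)])
K5 = _from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
TWO_EDGES = _from_edges(4, [(0, 1), (2, 3)])


class TestHandDerivedValues:
    def test_triangle_is_fully_clustered(self):
        assert clustering_coefficient(TRIANGLE)[0] == 1.0
        assert transitivity(TRIANGLE) == 1.0

    def test_path_graph_has_no_clustering(self):
        assert clustering_coefficient(P3)[0] == 0.0
        assert transitivity(P3) == 0.0

    def test_path_graph_enumerated_values(self):
        d = shortest_paths(P3)
        l, frac = characteristic_path_length(d)
        assert l == pytest.approx(4 / 3)
        assert frac == 1.0
        assert global_efficiency(d) == pytest.approx(5 / 6)
        assert local_efficiency(P3) == 0.0

    def test_k4_minus_edge(self):
        assert clustering_coefficient(K4_MINUS_EDGE)[0] == pytest.approx(5 / 6)
        assert transitivity(K4_MINUS_EDGE) == pytest.approx(0.75)

    def test_star_has_zero_local_efficiency(self):
        assert local_efficiency(STAR4) == 0.0

    def test_complete_graph_saturates_everything(self):
        d = shortest_paths(K5)
        assert characteristic_path_length(d)[0] == 1.0
        assert global_efficiency(d) == 1.0
        assert clustering_coefficient(K5)[0] == 1.0
        assert transitivity(K5) == 1.0
        assert local_efficiency(K5) == 1.0

    def test_fragmented_graph_uses_reachable_pairs_only(self):
        l, frac = characteristic_path_length(shortest_paths(TWO_EDGES))
        assert l == 1.0
        assert frac == pytest.approx(1 / 3)

    def test_empty_graph(self):
        empty = np.zeros((4, 4), dtype=np.uint8)
        d = shortest_paths(empty)
        assert global_efficiency(d) == 0.0
        l, frac = characteristic_path_length(d)
        assert np.isnan(l) and frac == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_all_metrics_match_brute_force_on_random_7_node_graphs(self, seed):
        rng = np.random.default_rng(seed)
        adj = oracles.random_graph(7, rng.uniform(0.2, 0.8), rng)
        m = small_world_metrics(adj)
        assert m.C == pytest.approx(oracles.brute_clustering(adj))
        assert m.T == pytest.approx(oracles.brute_transitivity(adj))
        assert m.GE == pytest.approx(oracles.brute_global_efficiency(adj))
        assert m.LE == pytest.approx(oracles.brute_local_efficiency(adj))
        l_oracle = oracles.brute_path_length(adj)
        assert (np.isnan(m.L) and np.isnan(l_oracle)) or m.L == pytest.approx(l_oracle)

    @pytest.mark.parametrize("seed", range(10))
    def test_metrics_match_networkx_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(12, 0.35, seed=seed)
        adj = nx.to_numpy_array(g)
        m = small_world_metrics(adj)
        assert m.C == pytest.approx(nx.average_clustering(g))
        assert m.T == pytest.approx(nx.transitivity(g))
        assert m.GE == pytest.approx(nx.global_efficiency(g))
        assert m.LE == pytest.approx(nx.local_efficiency(g))

    def test_shortest_paths_match_floyd_warshall(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            adj = oracles.random_graph(7, 0.3, rng)
            assert np.array_equal(shortest_paths(adj), oracles.floyd_warshall(adj))

    @pytest.mark.parametrize("seed", range(5))
    def test_isomorphism_invariance(self, seed):
        rng = np.random.default_rng(seed)
        adj = oracles.random_graph(10, 0.4, rng)
        perm = rng.permutation(10)
        relabeled = adj[np.ix_(perm, perm)]
        a, b = small_world_metrics(adj), small_world_metrics(relabeled)
        for field in ("C", "L", "GE", "LE", "T"):
            va, vb = getattr(a, field), getattr(b, field)
            assert va == pytest.approx(vb) or (np.isnan(va) and np.isnan(vb))

    def test_bounds_hold_across_a_sweep(self):
        rng = np.random.default_rng(23)
        z = rng.normal(size=(22, 22))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        for net in threshold_sweep(ZMatrix(z=z)):
            m = small_world_metrics(net)
            for val in (m.C, m.T, m.GE, m.LE):
                assert 0.0 <= val <= 1.0
            assert np.isnan(m.L) or m.L >= 1.0


class TestRandomReference:
    def test_degree_sequence_preserved_exactly(self):
        rng = np.random.default_rng(2)
        adj = oracles.random_graph(22, 0.3, rng)
        net = _net(adj)
        ref = random_reference(net, seed=5)
        assert np.array_equal(
            np.sort(ref.adjacency.sum(axis=0)), np.sort(adj.sum(axis=0))
        )
        assert np.all(np.diag(ref.adjacency) == 0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        net = _net(oracles.random_graph(22, 0.3, rng))
        a = random_reference(net, seed=11)
        b = random_reference(net, seed=11)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_ring_degree_sequence_preserved(self):
        ring = _from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        ref = random_reference(_net(ring), seed=0)
        assert np.array_equal(np.sort(ref.adjacency.sum(axis=0)), [2, 2, 2, 2])

    def test_rewiring_reduces_lattice_clustering(self):
        from motornet import make_group_network

        lattice = make_group_network(22, 88 / 231, 0.0, seed=0)
        c_lattice = clustering_coefficient(lattice)[0]
        c_refs = [
            clustering_coefficient(random_reference(_net(lattice), seed=s).adjacency)[0]
            for s in range(20)
        ]
        assert np.mean(c_refs) < c_lattice

    def test_too_few_edges_returns_copy_with_warning(self):
        single = _from_edges(4, [(0, 1)])
        with pytest.warns(UserWarning, match="fewer than 2 edges"):
            ref = random_reference(_net(single), seed=0)
        assert np.array_equal(ref.adjacency, single)


class TestNormalizedSmallWorld:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_graph_self_normalizes_to_unity(self, seed):
        rng = np.random.default_rng(seed)
        net = _net(oracles.random_graph(22, 0.5, rng))
        norm = normalized_small_world(net, n_random=20, seed=seed)
        assert 0.8 <= norm.gamma <= 1.2
        assert 0.95 <= norm.lam <= 1.05

    def test_ring_lattice_has_large_gamma(self):
        from motornet import make_group_network

        lattice = make_group_network(22, 44 / 231, 0.0, seed=0)
        norm = normalized_small_world(_net(lattice), n_random=20, seed=1)
        assert norm.gamma > 2.0

    def test_exact_reproducibility_and_delta_identity(self):
        rng = np.random.default_rng(7)
        net = _net(oracles.random_graph(22, 0.4, rng))
        a = normalized_small_world(net, n_random=1, seed=42)
        b = normalized_small_world(net, n_random=1, seed=42)
        assert (a.gamma, a.lam, a.delta) == (b.gamma, b.lam, b.delta)
        assert a.delta == pytest.approx(a.gamma / a.lam, abs=1e-12)


class TestMetricAuc:
    def test_constant_curve_is_rectangle(self):
        grid = np.linspace(0.3, 0.7, 41)
        assert metric_auc(np.full(41, 2.5), grid) == pytest.approx(0.4 * 2.5)

    def test_linear_ramp_is_triangle(self):
        grid = np.linspace(0.3, 0.7, 41)
        assert metric_auc(np.linspace(0, 1, 41), grid) == pytest.approx(0.2)

    def test_single_interval_trapezoid(self):
        assert metric_auc([1.0, 3.0], [0.3, 0.4]) == pytest.approx(0.2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metric_auc([1.0, 2.0], [0.3, 0.4, 0.5])


class TestSubjectProfile:
    def test_saturated_network_gives_unit_metrics(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(1.0, 2.0, size=(6, 6))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        nets = [
            proportional_threshold(ZMatrix(z=z), t) for t in (0.0, 0.01)
        ]  # both keep all 15 pairs on 6 nodes
        profile = subject_profile(nets, n_random=0)
        row = profile.curves.iloc[0]
        assert row["C"] == row["L"] == row["GE"] == row["T"] == 1.0

    def test_profile_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(22, 22))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        nets = threshold_sweep(ZMatrix(z=z), lo=0.3, hi=0.4, step=0.05)
        a = subject_profile(nets, n_random=5, seed=9)
        b = subject_profile(nets, n_random=5, seed=9)
        assert a.curves.equals(b.curves)
        assert a.auc.equals(b.auc)

    def test_base_only_mode_skips_normalized_metrics(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(10, 10))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        profile = subject_profile(threshold_sweep(ZMatrix(z=z)), n_random=0)
        assert list(profile.curves.columns) == ["C", "L", "GE", "LE", "T"]
        assert len(profile.auc) == 5
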