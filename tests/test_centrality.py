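"""Weighted centrality measures against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from symptomnet import (
    Battery,
    CentralityParams,
    Domain,
    Item,
    Orientation,
    SymptomNetwork,
    betweenness,
    blended_degree,
    centrality_table,
    closeness,
    degree_strength,
    shortest_paths,
)

from .oracles import (
    betweenness_oracle,
    closeness_oracle,
    enumerate_shortest_paths,
    random_weighted_graph,
)


def small_battery(n: int) -> Battery:
    items = tuple(
        Item(f"N{i}", f"node {i}", Domain.NEUROCOGNITIVE, 0, 100,
             Orientation.HIGHER_IS_BETTER)
        for i in range(n)
    )
    return Battery(items=items, name=f"small-{n}")


def net_from(w: np.ndarray) -> SymptomNetwork:
    return SymptomNetwork(battery=small_battery(w.shape[0]), weights=w)


class TestDegreeStrength:
    def test_isolated_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        k, s = degree_strength(net_from(w))
        assert k[2] == 0 and s[2] == 0

    def test_absolute_weights_in_strength(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = -0.3
        k, s = degree_strength(net_from(w))
        assert k[0] == 2
        assert s[0] == pytest.approx(0.8)

    def test_degree_matches_row_scan(self, make_network):
        rng = np.random.default_rng(21)
        w = random_weighted_graph(rng, 17, p_edge=0.3)
        k, _ = degree_strength(make_network(w))
        brute = [sum(1 for j in range(17) if j != i and w[i, j] != 0)
                 for i in range(17)]
        np.testing.assert_array_equal(k, brute)


class TestBlendedDegree:
    def test_alpha_limits_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            w = random_weighted_graph(rng, 10)
            k, s = degree_strength(net_from(w))
            np.testing.assert_array_equal(blended_degree(k, s, 0.0), k)
            np.testing.assert_array_equal(blended_degree(k, s, 1.0), s)

    def test_direct_evaluation(self):
        out = blended_degree(np.array([3.0]), np.array([1.5]), 0.5)
        assert out[0] == pytest.approx(np.sqrt(3 * 1.5))

    def test_isolated_node_zero_for_any_alpha(self):
        for a in (0.0, 0.5, 1.0, 2.0):
            assert blended_degree(np.array([0.0]), np.array([0.0]), a)[0] == 0.0


class TestShortestPaths:
    def test_single_edge(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.5
        paths = shortest_paths(net_from(w), CentralityParams(alpha=1.0))
        assert paths.distances[0, 1] == pytest.approx(2.0)

    def test_strong_detour_beats_weak_direct_tie(self):
        # A-C direct w=0.1 (cost 10) vs A-B-C with w=1 edges (cost 2)
        w = np.zeros((3, 3))
        w[0, 2] = w[2, 0] = 0.1
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        paths = shortest_paths(net_from(w))
        assert paths.distances[0, 2] == pytest.approx(2.0)
        assert paths.path_counts[0, 2] == 1

    def test_alpha_rescales_distances(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.5
        d1 = shortest_paths(net_from(w), CentralityParams(alpha=1.0)).distances[0, 1]
        d2 = shortest_paths(net_from(w), CentralityParams(alpha=2.0)).distances[0, 1]
        assert d2 == pytest.approx(d1 ** 2)

    def test_unreachable_is_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        paths = shortest_paths(net_from(w))
        assert np.isinf(paths.distances[0, 2])
        assert paths.path_counts[0, 2] == 0

    def test_tied_paths_counted(self):
        # two equal-cost routes 0-1-3 and 0-2-3
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 3), (0, 2), (2, 3)]:
            w[i, j] = w[j, i] = 0.5
        paths = shortest_paths(net_from(w))
        assert paths.path_counts[0, 3] == 2
        assert paths.through_counts[1, 0, 3] == 1
        assert paths.through_counts[2, 0, 3] == 1


class TestBetweennessCloseness:
    def test_star_hub(self):
        w = np.zeros((5, 5))
        for leaf in range(1, 5):
            w[0, leaf] = w[leaf, 0] = 1.0
        paths = shortest_paths(net_from(w))
        cb = betweenness(paths)
        assert cb[0] == pytest.approx(6.0)  # C(4, 2)
        np.testing.assert_allclose(cb[1:], 0.0)

    def test_complete_graph_zero_betweenness(self):
        w = np.ones((5, 5)) - np.eye(5)
        cb = betweenness(shortest_paths(net_from(w)))
        np.testing.assert_allclose(cb, 0.0)

    def test_tied_paths_split_credit(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 3), (0, 2), (2, 3)]:
            w[i, j] = w[j, i] = 0.5
        cb = betweenness(shortest_paths(net_from(w)))
        assert cb[1] == pytest.approx(0.5)
        assert cb[2] == pytest.approx(0.5)

    def test_two_node_closeness(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 1.0
        cc = closeness(shortest_paths(net_from(w)))
        np.testing.assert_allclose(cc, [1.0, 1.0])

    def test_three_node_path_closeness(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        cc = closeness(shortest_paths(net_from(w)))
        assert cc[1] == pytest.approx(1 / 2)
        assert cc[0] == pytest.approx(1 / 3)

    def test_matches_networkx_on_tie_free_graphs(self):
        """Independent cross-check: continuous random weights almost surely
        have no tied shortest paths, where networkx's Brandes betweenness
        must agree exactly."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            w = random_weighted_graph(rng, n, p_edge=0.6)
            net = net_from(w)
            cb = betweenness(shortest_paths(net))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if w[i, j] != 0:
                        g.add_edge(i, j, dist=1.0 / abs(w[i, j]))
            ref = nx.betweenness_centrality(g, weight="dist", normalized=False)
            np.testing.assert_allclose(cb, [ref[i] for i in range(n)], atol=1e-9)


class TestOracleEquivalence:
    def test_random_graphs_match_enumeration(self):
        """Distances, path counts, betweenness and closeness all agree with
        exhaustive simple-path enumeration on small random graphs."""
        rng = np.random.default_rng(1234)
        for rep in range(60):
            n = int(rng.integers(3, 8))
            w = random_weighted_graph(rng, n, p_edge=float(rng.uniform(0.3, 0.9)))
            alpha = float(rng.choice([0.5, 1.0, 2.0]))
            net = net_from(w)
            paths = shortest_paths(net, CentralityParams(alpha=alpha))
            dist_o, counts_o, _ = enumerate_shortest_paths(w, alpha)
            np.testing.assert_allclose(paths.distances, dist_o, rtol=1e-9)
            np.testing.assert_array_equal(paths.path_counts, counts_o)
            np.testing.assert_allclose(
                betweenness(paths), betweenness_oracle(w, alpha), atol=1e-9)
            np.testing.assert_allclose(
                closeness(paths), closeness_oracle(w, alpha), rtol=1e-9)


class TestScaleCovariance:
    def test_weight_scaling_laws(self):
        """Scaling all weights by c>0 scales distances by c^-a, leaves
        betweenness invariant, and scales closeness by c^a."""
        rng = np.random.default_rng(77)
        w = random_weighted_graph(rng, 7, p_edge=0.7)
        c, alpha = 2.5, 1.5
        params = CentralityParams(alpha=alpha)
        base = shortest_paths(net_from(w), params)
        scaled = shortest_paths(net_from(np.clip(c * w, -1e9, 1e9)), params)
        np.testing.assert_allclose(scaled.distances,
                                   base.distances * c ** (-alpha), rtol=1e-9)
        np.testing.assert_allclose(betweenness(scaled), betweenness(base),
                                   atol=1e-9)
        np.testing.assert_allclose(closeness(scaled),
                                   closeness(base) * c ** alpha, rtol=1e-9)

    def test_degree_one_node_has_zero_betweenness(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            w = random_weighted_graph(rng, 7, p_edge=0.5)
            # force node 0 to have exactly one edge
            w[0, :] = w[:, 0] = 0.0
            w[0, 1] = w[1, 0] = 0.7
            cb = betweenness(shortest_paths(net_from(w)))
            assert cb[0] == 0.0


class TestCentralityTable:
    def test_empty_network_all_zero(self, make_network):
        df = centrality_table(make_network(np.zeros((17, 17))))
        raw = ["degree", "strength", "blended_degree", "betweenness", "closeness"]
        assert (df[raw].to_numpy() == 0).all()
        assert (df[[f"z_{c}" for c in raw]].to_numpy() == 0).all()

    def test_standardized_columns_centered(self, make_network):
        rng = np.random.default_rng(13)
        w = random_weighted_graph(rng, 17, p_edge=0.4)
        df = centrality_table(make_network(w))
        for col in ["z_degree", "z_strength", "z_betweenness", "z_closeness"]:
            assert abs(df[col].mean()) < 1e-12
            if df[col].std(ddof=0) > 0:
                assert df[col].std(ddof=0) == pytest.approx(1.0)

    def test_node_order_follows_battery(self, battery, make_network):
        df = centrality_table(make_network(np.zeros((17, 17))))
        assert df.index.tolist() == battery.labels
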