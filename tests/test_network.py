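import math

import networkx as nx
import numpy as np
import pytest

import trajnet as tn
from trajnet.dccm import DCCMatrix
from trajnet.network import WEIGHT_RTOL

from _oracles import (
    brute_betweenness,
    brute_closeness,
    brute_k_shortest,
    brute_shortest_distance,
    random_weighted_graph,
)


def dccm_from(matrix):
    m = np.asarray(matrix, float)
    return DCCMatrix(matrix=m, resnums=np.arange(1, len(m) + 1))


class TestBuildNetwork:
    def test_closed_form_weight(self):
        g = tn.build_network(dccm_from([[1, 0.5], [0.5, 1]]), c_thr=0.3)
        assert g.number_of_edges() == 1
        assert g[1][2]["weight"] == pytest.approx(math.log(2), abs=1e-12)

    def test_unit_correlation_zero_weight(self):
        g = tn.build_network(dccm_from([[1, 1.0], [1.0, 1]]), c_thr=0.3)
        assert g[1][2]["weight"] == 0.0

    def test_subthreshold_edge_dropped(self):
        g = tn.build_network(dccm_from([[1, 0.2], [0.2, 1]]), c_thr=0.3)
        assert g.number_of_edges() == 0

    def test_magnitude_vs_signed_anticorrelation(self):
        m = dccm_from([[1, -0.6], [-0.6, 1]])
        assert tn.build_network(m, 0.3, "magnitude").number_of_edges() == 1
        assert tn.build_network(m, 0.3, "signed").number_of_edges() == 0

    def test_raising_threshold_never_adds_edges(self, rng):
        for _ in range(10):
            c = np.clip(rng.uniform(-1, 1, size=(12, 12)), -1, 1)
            c = 0.5 * (c + c.T)
            np.fill_diagonal(c, 1.0)
            d = dccm_from(c)
            e03 = tn.build_network(d, 0.3).number_of_edges()
            e05 = tn.build_network(d, 0.5).number_of_edges()
            assert e05 <= e03

    def test_log_base_rescales_but_preserves_rankings(self, rng):
        """Changing log base multiplies every distance by a constant:
        rankings and shortest-path trees are unchanged by construction."""
        c = 0.5 * (rng.uniform(0.3, 0.99, (8, 8)) + rng.uniform(0.3, 0.99, (8, 8)).T)
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 1.0)
        g = tn.build_network(dccm_from(c), 0.3)
        g2 = g.copy()
        for u, v in g2.edges:
            g2[u][v]["weight"] = g2[u][v]["weight"] / math.log(10)  # log10 weights
        b1 = tn.betweenness_centrality(g)
        b2 = tn.betweenness_centrality(g2)
        rank = lambda b: sorted(b, key=lambda v: (-b[v], v))
        assert rank(b1) == rank(b2)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            tn.build_network(dccm_from(np.eye(2)), c_thr=1.0)


class TestDegree:
    def test_triangle_and_star(self, star4):
        tri = nx.complete_graph(3)
        nx.set_edge_attributes(tri, 1.0, "weight")
        assert set(tn.degree_centrality(tri).values()) == {2}
        d = tn.degree_centrality(star4)
        assert d[0] == 3 and d[1] == d[2] == d[3] == 1

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            g = random_weighted_graph(rng)
            d = tn.degree_centrality(g)
            for v in g:
                assert d[v] == sum(1 for _ in g.edges(v))


class TestCloseness:
    def test_path_graph_hand_values(self, path3):
        c = tn.closeness_centrality(path3)
        assert c[1] == pytest.approx(1.0)
        assert c[0] == pytest.approx(2 / 3)

    def test_distance_rescaling(self, path3):
        for u, v in path3.edges:
            path3[u][v]["weight"] = 0.5
        c = tn.closeness_centrality(path3)
        assert c[1] == pytest.approx(2.0)

    def test_complete_graph_uniform(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.25, "weight")
        c = tn.closeness_centrality(g)
        assert all(v == pytest.approx(4.0) for v in c.values())

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            g = random_weighted_graph(rng, n_max=7)
            mine = tn.closeness_centrality(g)
            oracle = brute_closeness(g)
            for v in g:
                assert mine[v] == pytest.approx(oracle[v], abs=1e-9)


class TestBetweenness:
    def test_path_graph_all_pairs_normalization(self, path3):
        b = tn.betweenness_centrality(path3, "all-pairs")
        assert b[1] == pytest.approx(1 / 3)
        assert b[0] == b[2] == 0.0

    def test_star_all_pairs_normalization(self, star4):
        b = tn.betweenness_centrality(star4, "all-pairs")
        assert b[0] == pytest.approx(0.5)

    def test_standard_normalization_scales(self, star4):
        b = tn.betweenness_centrality(star4, "standard")
        assert b[0] == pytest.approx(1.0)  # 3 pairs / 3

    def test_cycle_graph_tied_paths(self):
        g = nx.cycle_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        b = tn.betweenness_centrality(g, "all-pairs")
        # each opposite pair has 2 tied paths; each interior node carries 1/2
        assert all(v == pytest.approx(0.5 / 6) for v in b.values())

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            g = random_weighted_graph(rng)
            for norm in ("all-pairs", "standard"):
                mine = tn.betweenness_centrality(g, norm)
                oracle = brute_betweenness(g, norm)
                for v in g:
                    assert mine[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_matches_networkx_brandes(self, rng):
        """Independent cross-check against the networkx implementation
        (standard normalization, no ties in random float weights)."""
        for _ in range(20):
            g = random_weighted_graph(rng)
            mine = tn.betweenness_centrality(g, "standard")
            ref = nx.betweenness_centrality(g, weight="weight", normalized=True)
            for v in g:
                assert mine[v] == pytest.approx(ref[v], abs=1e-9)

    def test_permutation_equivariance(self, rng):
        g = random_weighted_graph(rng)
        perm = {v: 100 + v for v in g}
        h = nx.relabel_nodes(g, perm)
        bg = tn.betweenness_centrality(g)
        bh = tn.betweenness_centrality(h)
        for v in g:
            assert bg[v] == pytest.approx(bh[perm[v]], abs=1e-12)

    def test_pair_sum_identity(self, rng):
        """Sum of unnormalised betweenness over nodes equals the sum over
        pairs of the tie-averaged interior-node count of shortest paths."""
        for _ in range(10):
            g = random_weighted_graph(rng, n_max=6)
            n = g.number_of_nodes()
            b = tn.betweenness_centrality(g, "all-pairs")
            total = sum(b.values()) * (n * (n - 1) / 2)
            expected = 0.0
            import itertools

            from _oracles import all_simple_paths_weights

            for s, t in itertools.combinations(g.nodes, 2):
                paths = all_simple_paths_weights(g, s, t)
                if not paths:
                    continue
                best = min(w for _, w in paths)
                tied = [p for p, w in paths if w <= best + WEIGHT_RTOL]
                expected += sum(len(p) - 2 for p in tied) / len(tied)
            assert total == pytest.approx(expected, abs=1e-9)

    def test_zero_weight_edges_finite(self):
        g = nx.path_graph(4)
        nx.set_edge_attributes(g, 0.0, "weight")
        b = tn.betweenness_centrality(g, "all-pairs")
        assert all(np.isfinite(v) for v in b.values())


class TestShortestPaths:
    def test_zero_weight_chain_all_zero(self):
        g = nx.path_graph(4)
        nx.set_edge_attributes(g, 0.0, "weight")
        d = tn.shortest_path_lengths(g, 0)
        assert all(v == 0.0 for v in d.values())

    def test_diamond_hand_computation(self, diamond):
        d = tn.shortest_path_lengths(diamond, 0)
        assert d[3] == pytest.approx(2.0)  # via node 1, not node 2
        assert d[2] == pytest.approx(1.0)

    def test_disconnected_is_infinite(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        d = tn.shortest_path_lengths(g, 0)
        assert d[1] == math.inf

    def test_unknown_source_is_error(self, diamond):
        with pytest.raises(KeyError):
            tn.shortest_path_lengths(diamond, 99)

    def test_matches_enumeration(self, rng):
        for _ in range(20):
            g = random_weighted_graph(rng, n_max=6)
            s = min(g.nodes)
            d = tn.shortest_path_lengths(g, s)
            for t in g:
                if t != s:
                    assert d[t] == pytest.approx(
                        brute_shortest_distance(g, s, t), abs=1e-9
                    )


class TestCommunities:
    def test_two_cliques_split(self):
        g = nx.Graph()
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(base + i, base + j, weight=0.1)
        g.add_edge(0, 5, weight=3.0)  # long bridge
        part = tn.detect_communities(g)
        assert part.n_communities == 2
        assert len({part.labels[i] for i in range(5)}) == 1

    def test_edgeless_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(7))
        part = tn.detect_communities(g)
        assert part.n_communities == 7
        assert part.modularity == 0.0

    def test_planted_partition_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for seed in range(20):
            g = tn.planted_partition_graph(
                tn.PlantedPartitionConfig(
                    sizes=(12, 12), p_in=0.9, p_out=0.02, seed=seed
                )
            )
            part = tn.detect_communities(g)
            truth = g.graph["ground_truth"]
            nodes = sorted(g.nodes)
            scores.append(
                adjusted_rand_score(
                    [truth[v] for v in nodes], [part.labels[v] for v in nodes]
                )
            )
        assert np.mean(scores) > 0.9


class TestSuboptimalPaths:
    def test_k1_is_dijkstra_shortest(self, diamond):
        ps = tn.suboptimal_paths(diamond, 0, 3, k=1)
        assert ps.paths == [[0, 1, 3]]
        assert ps.weights[0] == pytest.approx(2.0)

    def test_diamond_ordering(self, diamond):
        ps = tn.suboptimal_paths(diamond, 0, 3, k=5)
        assert ps.paths == [[0, 1, 3], [0, 2, 3]]
        assert ps.weights == pytest.approx([2.0, 3.0])

    def test_no_path_returns_empty(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        ps = tn.suboptimal_paths(g, 0, 1, k=3)
        assert len(ps) == 0

    def test_matches_brute_enumeration(self, rng):
        for _ in range(30):
            g = random_weighted_graph(rng, n_max=7)
            nodes = sorted(g.nodes)
            s, t = nodes[0], nodes[-1]
            ps = tn.suboptimal_paths(g, s, t, k=5)
            oracle = brute_k_shortest(g, s, t, 5)
            assert [w for _, w in oracle] == pytest.approx(ps.weights, abs=1e-9)

    def test_weights_non_decreasing_and_loopless(self, rng):
        g = random_weighted_graph(rng, n_max=8, p=0.7)
        nodes = sorted(g.nodes)
        ps = tn.suboptimal_paths(g, nodes[0], nodes[-1], k=10)
        assert ps.weights == sorted(ps.weights)
        for p in ps.paths:
            assert len(p) == len(set(p))


class TestReportAndComparison:
    def test_top_residues_star(self, star4):
        rep = tn.centrality_report(star4)
        top = tn.top_residues(rep, "degree", 1)
        assert top["residue"].item() == 0

    def test_tie_broken_by_residue_number(self):
        g = nx.Graph()
        g.add_edge(10, 20, weight=1.0)
        rep = tn.centrality_report(g)
        top = tn.top_residues(rep, "degree", 2)
        assert list(top["residue"]) == [10, 20]

    def test_k_larger_than_n_warns(self, star4):
        rep = tn.centrality_report(star4)
        with pytest.warns(UserWarning):
            top = tn.top_residues(rep, "betweenness", 10)
        assert len(top) == 4

    def test_identical_networks_no_difference(self, diamond):
        comp = tn.compare_networks(diamond, diamond)
        assert (comp.per_node.filter(like="d_").to_numpy() == 0).all()
        assert comp.communities_a == comp.communities_b
        assert comp.edges_only_a == [] and comp.edges_only_b == []

    def test_hub_removal_shows_largest_betweenness_drop(self, star4):
        reduced = star4.copy()
        reduced.remove_edges_from(list(star4.edges(0)))
        comp = tn.compare_networks(star4, reduced)
        assert comp.max_shift_residue("betweenness") == 0

    def test_disjoint_node_sets_error(self, star4, path3):
        g = nx.relabel_nodes(path3, {0: 100, 1: 101, 2: 102})
        with pytest.raises(ValueError, match="symmetric difference"):
            tn.compare_networks(star4, g)
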