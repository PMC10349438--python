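"""Directed interaction networks: census identities, metrics, oracles."""

import numpy as np
import pytest

from oracles import hits_eig_oracle, hits_spectral_gap, path_oracle
from sociorank.ethogram import CountMatrix
from sociorank.network import (
    EmptyGraphError,
    build_graph,
    counts_from_census,
    dyad_census,
    export_edgelist,
    graph_metrics,
    hits_scores,
    network_panel,
    node_strengths,
    path_metrics,
)


def cm_from(counts, category="agonistic", period="pre"):
    counts = np.asarray(counts)
    animals = tuple(chr(ord("A") + i) for i in range(counts.shape[0]))
    return CountMatrix(animals, counts, category, period)


def random_cm(rng, n=None, p=0.35, wmax=5):
    n = n or int(rng.integers(3, 10))
    w = (rng.random((n, n)) < p) * rng.integers(1, wmax + 1, size=(n, n))
    np.fill_diagonal(w, 0)
    return cm_from(w)


class TestBuildGraph:
    def test_inactive_animals_are_excluded(self):
        g = build_graph(cm_from([[0, 3, 0], [1, 0, 0], [0, 0, 0]]))
        assert set(g.nodes) == {"A", "B"}
        assert g["A"]["B"]["weight"] == 3 and g["B"]["A"]["weight"] == 1

    def test_full_roster_mode_keeps_isolates(self):
        g = build_graph(cm_from([[0, 3, 0], [1, 0, 0], [0, 0, 0]]), active_only=False)
        assert set(g.nodes) == {"A", "B", "C"}

    def test_all_zero_matrix_raises(self):
        with pytest.raises(EmptyGraphError):
            build_graph(cm_from(np.zeros((3, 3), dtype=int)))


class TestDyadCensus:
    def test_complete_triangle_all_mutual(self):
        c = dyad_census(build_graph(cm_from(1 - np.eye(3, dtype=int))))
        assert (c.mutual, c.asym, c.null) == (3, 0, 0)

    def test_single_directed_edge(self):
        c = dyad_census(build_graph(cm_from([[0, 2], [0, 0]])))
        assert (c.mutual, c.asym, c.null) == (0, 1, 0)

    def test_census_identities_on_random_graphs(self, rng):
        for _ in range(50):
            g = build_graph(random_cm(rng)) if rng.random() < 0.9 else None
            if g is None:
                continue
            n, e = g.number_of_nodes(), g.number_of_edges()
            c = dyad_census(g)
            assert c.mutual + c.asym + c.null == n * (n - 1) // 2
            assert 2 * c.mutual + c.asym == e


class TestGraphMetrics:
    def test_complete_digraph_density_and_reciprocity_are_one(self):
        m = graph_metrics(build_graph(cm_from(1 - np.eye(5, dtype=int))))
        assert m.density == 1.0 and m.reciprocity == 1.0

    def test_published_panel_identities_from_census(self):
        """A 14-node graph with census (17, 64, 10) reproduces the study's
        pre-castration agonistic panel: 98 connections, density 0.54,
        reciprocity 0.35."""
        g = build_graph(counts_from_census(14, mutual=17, asym=64))
        m = graph_metrics(g)
        c = dyad_census(g)
        assert m.connections == 98
        assert (c.mutual, c.asym, c.null) == (17, 64, 10)
        assert round(m.density, 2) == 0.54
        assert round(m.reciprocity, 2) == 0.35

    def test_active_node_convention_shrinks_the_denominator(self):
        """With 2 of 14 roster animals inactive, density is computed over
        12 nodes — the only reading under which the study's affiliative
        panel (51 edges, density 0.39, null 33) is internally consistent."""
        cm = counts_from_census(12, mutual=18, asym=15, n_inactive=2)
        g = build_graph(cm)
        m = graph_metrics(g)
        assert g.number_of_nodes() == 12 and m.connections == 51
        assert round(m.density, 2) == 0.39
        full = build_graph(cm, active_only=False)
        assert full.number_of_nodes() == 14

    def test_tournament_reciprocity_is_zero(self):
        cm = counts_from_census(10, mutual=0, asym=17)
        assert graph_metrics(build_graph(cm)).reciprocity == 0.0


class TestPathMetrics:
    def test_two_hop_chain_single_intermediary(self):
        pm = path_metrics(build_graph(cm_from([[0, 1, 0], [0, 0, 1], [0, 0, 0]])), "unweighted")
        assert pm.betweenness == {"A": 0.0, "B": 1.0, "C": 0.0}
        assert pm.diameter == 2

    def test_complete_digraph_betweenness_zero(self):
        pm = path_metrics(build_graph(cm_from(1 - np.eye(6, dtype=int))), "unweighted")
        assert all(b == 0.0 for b in pm.betweenness.values())

    def test_unreachable_distance_substituted_with_node_count(self):
        # A -> B only: from B nothing is reachable, d(B, A) := n = 2
        pm = path_metrics(build_graph(cm_from([[0, 3], [0, 0]])), "unweighted")
        assert pm.closeness["B"] == pytest.approx(1 / 2)
        assert pm.closeness["A"] == pytest.approx(1 / 1)

    def test_unknown_distance_mode_raises(self):
        g = build_graph(cm_from([[0, 1], [0, 0]]))
        with pytest.raises(ValueError, match="distance_mode"):
            path_metrics(g, "hops")

    def test_matches_brute_force_oracle_on_random_digraphs(self, rng):
        checked = 0
        while checked < 25:
            cm = random_cm(rng)
            if cm.counts.sum() == 0:
                continue
            g = build_graph(cm, active_only=False)
            n = len(cm.animals)
            for mode in ("unweighted", "weight_as_distance"):
                pm = path_metrics(g, mode)
                orc = path_oracle(cm.counts.astype(float), mode)
                assert pm.diameter == pytest.approx(orc["diameter"])
                for i, a in enumerate(cm.animals):
                    assert pm.betweenness[a] == pytest.approx(orc["betweenness"][i], abs=1e-8)
                    assert pm.closeness[a] == pytest.approx(orc["closeness"][i], abs=1e-10)
            checked += 1


class TestHits:
    def test_single_edge(self):
        hub, auth = hits_scores(build_graph(cm_from([[0, 2], [0, 0]])))
        assert hub == {"A": 1.0, "B": 0.0}
        assert auth == {"A": 0.0, "B": 1.0}

    def test_out_star_leaves_share_maximal_authority(self):
        cm = cm_from([[0, 1, 1, 1], [0] * 4, [0] * 4, [0] * 4])
        hub, auth = hits_scores(build_graph(cm))
        assert hub["A"] == 1.0
        assert auth["B"] == auth["C"] == auth["D"] == 1.0

    def test_matches_eigen_oracle_and_weight_scale_invariance(self, rng):
        import networkx as nx

        checked = 0
        while checked < 20:
            n = int(rng.integers(3, 8))
            mask = rng.random((n, n)) < 0.5
            np.fill_diagonal(mask, False)
            w = mask * rng.uniform(0.5, 5.0, size=(n, n))
            if w.sum() == 0 or hits_spectral_gap(w) < 1e-6:
                continue
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(n):
                    if w[i, j] > 0:
                        g.add_edge(i, j, weight=w[i, j])
            hub, auth = hits_scores(g)
            oh, oa = hits_eig_oracle(w)
            assert np.allclose([hub[i] for i in range(n)], oh, atol=1e-8)
            assert np.allclose([auth[i] for i in range(n)], oa, atol=1e-8)

            g2 = nx.DiGraph()
            g2.add_nodes_from(range(n))
            g2.add_edges_from(
                (u, v, {"weight": 7.5 * d["weight"]}) for u, v, d in g.edges(data=True)
            )
            hub2, auth2 = hits_scores(g2)
            assert np.allclose(
                [hub[i] for i in range(n)], [hub2[i] for i in range(n)], atol=1e-9
            )
            checked += 1

    def test_edgeless_graph_raises(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("A")
        with pytest.raises(EmptyGraphError):
            hits_scores(g)


class TestNodeStrengths:
    def test_strengths_are_weighted_sums(self):
        g = build_graph(cm_from([[0, 3], [1, 0]]))
        din, dout, dall = node_strengths(g)
        assert (din["A"], dout["A"], dall["A"]) == (1, 3, 4)

    def test_handshake_and_matrix_sum_oracle(self, rng):
        for _ in range(20):
            cm = random_cm(rng)
            if cm.counts.sum() == 0:
                continue
            g = build_graph(cm)
            din, dout, dall = node_strengths(g)
            assert sum(dall.values()) == 2 * cm.counts.sum()
            for a in g.nodes:
                i = cm.animals.index(a)
                assert din[a] == cm.counts[:, i].sum()
                assert dout[a] == cm.counts[i, :].sum()


class TestNetworkPanel:
    def test_panel_is_internally_consistent(self, rng):
        cm = random_cm(rng, n=8)
        cm.counts[0, 1] = 2  # guarantee non-empty
        panel = network_panel(cm_from(cm.counts))
        nodes = panel.nodes
        assert panel.connections == 2 * panel.mutual + panel.asym
        assert (nodes["degree_all"] == nodes["degree_in"] + nodes["degree_out"]).all()
        assert nodes["hub_score"].max() == pytest.approx(1.0)
        assert nodes["authority_score"].max() == pytest.approx(1.0)
        assert (nodes >= 0).all().all()
        assert 0 <= panel.density <= 1 and 0 <= panel.reciprocity <= 1

    def test_edgelist_export_roundtrip(self):
        g = build_graph(cm_from([[0, 3], [1, 0]]))
        df = export_edgelist(g)
        assert set(map(tuple, df.values)) == {("A", "B", 3), ("B", "A", 1)}
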