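"""Shared-OTU networks and spinglass community consensus."""

import numpy as np
import pandas as pd
import pytest

from ecotransect.centroids import otu_memberships, representative_otus
from ecotransect.errors import ConfigurationError
from ecotransect.network import (
    build_network,
    exhaustive_min_hamiltonian,
    network_summary,
    rb_hamiltonian,
    spinglass_communities,
)


class TestBuildNetwork:
    def test_intersection_weights(self):
        G = build_network({"a": {"A", "B", "C"}, "b": {"B", "C", "D"}})
        assert G["a"]["b"]["weight"] == 2

    def test_disjoint_pools_carry_no_edge(self):
        G = build_network({"a": {"A"}, "b": {"B"}, "c": {"A", "B"}})
        assert not G.has_edge("a", "b")
        assert G.degree("c") == 2

    def test_duplicate_node_ids_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            build_network([("a", {"A"}), ("a", {"B"})])

    @pytest.mark.parametrize("seed", range(3))
    def test_weight_bounded_by_smaller_pool(self, seed):
        rng = np.random.default_rng(seed)
        pools = {
            i: set(rng.choice(50, size=rng.integers(1, 20), replace=False).tolist())
            for i in range(6)
        }
        G = build_network(pools)
        for u, v, w in G.edges(data="weight"):
            assert 0 < w <= min(len(pools[u]), len(pools[v]))

    def test_tau_sweep_never_increases_weights(self, rng):
        C = pd.DataFrame(rng.gamma(0.4, 1.0, (4, 80)),
                         index=["C0", "C1", "C2", "C3"],
                         columns=[f"o{i}" for i in range(80)])
        shares = otu_memberships(C)
        prev = None
        for tau in (0.5, 0.75, 0.85, 0.95):
            pools = representative_otus(shares, tau)
            weights = {
                (a, b): len(pools[a] & pools[b])
                for a in pools for b in pools if a < b
            }
            if prev is not None:
                assert all(weights[e] <= prev[e] for e in weights)
            prev = weights


def two_cliques_graph():
    """Two weighted 3-cliques joined by a single weak edge."""
    pools = None  # adjacency given directly
    import networkx as nx

    G = nx.Graph()
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i < j:
                    G.add_edge(i, j, weight=3.0)
    G.add_edge(2, 3, weight=1.0)
    return G


class TestSpinglass:
    def test_two_cliques_split_is_the_energy_minimum(self):
        import networkx as nx

        G = two_cliques_graph()
        A = nx.to_numpy_array(G, nodelist=sorted(G), weight="weight")
        h_min, labels = exhaustive_min_hamiltonian(A)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        # the split strictly beats one community and the wrong split
        assert h_min < rb_hamiltonian(A, np.zeros(6))
        assert h_min < rb_hamiltonian(A, np.array([0, 0, 1, 1, 0, 1]))

    def test_annealer_finds_two_cliques(self):
        G = two_cliques_graph()
        cons = spinglass_communities(G, n_runs=100, seed=5)
        parts = sorted(map(tuple, (sorted(c) for c in cons.communities())))
        assert parts == [(0, 1, 2), (3, 4, 5)]
        assert cons.modal_frequency >= 0.99

    def test_agrees_with_igraph_spinglass_on_clear_structure(self):
        import igraph as ig
        import random

        G = two_cliques_graph()
        cons = spinglass_communities(G, n_runs=20, seed=7)
        g = ig.Graph(n=6, edges=list(G.edges))
        weights = [G[u][v]["weight"] for u, v in G.edges]
        random.seed(0)
        ref = g.community_spinglass(weights=weights, spins=6).membership
        ours = dict(zip(cons.nodes, cons.modal_labels))
        ours_sets = {frozenset(c) for c in cons.communities()}
        ref_sets = set()
        for lab in set(ref):
            ref_sets.add(frozenset(i for i in range(6) if ref[i] == lab))
        assert ours_sets == ref_sets
        assert len(ours) == 6

    def test_complete_graph_is_one_community(self):
        import networkx as nx

        G = nx.complete_graph(6)
        cons = spinglass_communities(G, n_runs=50, seed=1)
        assert len(set(cons.modal_labels)) == 1

    def test_minor_components_reported_as_isolates(self):
        import networkx as nx

        G = two_cliques_graph()
        G.add_edge("x", "y", weight=1.0)
        cons = spinglass_communities(G, n_runs=20, seed=2)
        assert set(cons.isolates) == {"x", "y"}

    def test_empty_network_rejected(self):
        import networkx as nx

        with pytest.raises(ConfigurationError):
            spinglass_communities(nx.Graph())

    def test_planted_two_blocks_recovered(self, rng):
        import networkx as nx

        G = nx.Graph()
        blocks = [list(range(5)), list(range(5, 10))]
        for block in blocks:
            for i in block:
                for j in block:
                    if i < j and rng.random() < 0.9:
                        G.add_edge(i, j, weight=rng.integers(5, 10))
        for i in blocks[0]:
            for j in blocks[1]:
                if rng.random() < 0.3:
                    G.add_edge(i, j, weight=1)
        cons = spinglass_communities(G, n_runs=100, seed=3)
        comms = [frozenset(c) for c in cons.communities()]
        assert frozenset(blocks[0]) in comms and frozenset(blocks[1]) in comms
        assert cons.modal_frequency >= 0.95


class TestSummary:
    def test_identical_pools_fully_shared(self):
        pools = {("Jan", "STW"): {"A", "B"}, ("Jul", "STW"): {"A", "B"}}
        month_otus = {"Jan": {"A", "B", "C"}, "Jul": {"A", "B", "C"}}
        s = network_summary(pools, month_otus, {"A", "B", "C", "D"})
        assert s["shared_pct_per_cluster"][("Jan", "STW")] == 100.0
        assert s["present_pct_per_month"]["Jan"] == 75.0
        assert s["shared_pct_per_month"]["Jan"] == 100.0

    def test_disjoint_pools_unshared(self):
        pools = {("Jan", "STW"): {"A"}, ("Jul", "STW"): {"B"}}
        month_otus = {"Jan": {"A"}, "Jul": {"B"}}
        s = network_summary(pools, month_otus, {"A", "B"})
        assert s["shared_pct_per_cluster"][("Jan", "STW")] == 0.0
        assert s["shared_pct_per_month"]["Jan"] == 0.0
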