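"""Co-occurrence network inference and link-count normalization."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oxevo import synth
from oxevo.cooccur import (
    CooccurrenceNetwork,
    export_network,
    normalized_link_counts,
    pearson_network,
    read_network,
    sparcc_network,
)


def _table(counts, features=None):
    features = features or [f"f{i}" for i in range(len(counts))]
    samples = [f"s{j}" for j in range(len(counts[0]))]
    return pd.DataFrame(counts, index=features, columns=samples)


class TestPearsonNetwork:
    def test_identical_profiles_give_perfect_edge(self):
        row = [10, 40, 160, 640, 20, 80]
        counts = _table([row, row, [7, 7, 7, 9, 8, 7], [100, 50, 20, 10, 60, 30]])
        net = pearson_network(counts, alpha=0.05, r_min=0.4)
        assert net.graph.has_edge("f0", "f1")
        assert net.graph["f0"]["f1"]["r"] == pytest.approx(1.0)

    def test_planted_pair_recovered(self):
        feats = [f"f{i}" for i in range(8)]
        table, _ = synth.simulate_abundance(
            feats, [(("f0", "f1"), 0.9)], n_samples=200, depth=5000, seed=1
        )
        net = pearson_network(table)
        assert net.graph.has_edge("f0", "f1")

    def test_null_table_mostly_clean(self):
        """Independent features at a realistic panel size yield almost no
        edges; tiny panels would instead show compositional-closure
        artifacts (strong spurious negative correlations)."""
        hits = 0
        for seed in range(20):
            feats = [f"f{i}" for i in range(30)]
            table, _ = synth.simulate_abundance(feats, [], n_samples=200, depth=5000, seed=seed)
            net = pearson_network(table)
            hits += net.graph.number_of_edges() > 0
        assert hits <= 3

    def test_edge_filter_monotone(self):
        feats = [f"f{i}" for i in range(10)]
        table, _ = synth.simulate_abundance(
            feats, [(("f0", "f1"), 0.9), (("f2", "f3"), 0.6)],
            n_samples=100, depth=5000, seed=3,
        )
        loose = pearson_network(table, alpha=0.10, r_min=0.3)
        tight_r = pearson_network(table, alpha=0.10, r_min=0.6)
        tight_a = pearson_network(table, alpha=0.01, r_min=0.3)
        assert set(tight_r.graph.edges) <= set(loose.graph.edges)
        assert set(tight_a.graph.edges) <= set(loose.graph.edges)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson_network(_table([[1, 2, 3]] * 4))

    def test_constant_feature_excluded_with_warning(self):
        counts = _table(
            [[5, 5, 5, 5, 5], [1, 9, 3, 7, 5], [2, 4, 8, 16, 32], [9, 3, 1, 7, 5]]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            net = pearson_network(counts)
        assert "f0" not in net.graph.nodes


class TestSparccNetwork:
    def test_planted_pair_correlation_recovered(self):
        feats = [f"f{i}" for i in range(20)]
        table, _ = synth.simulate_abundance(
            feats, [(("f0", "f1"), 0.9)], n_samples=100, depth=10_000, seed=2
        )
        net = sparcc_network(table, n_permutations=20, seed=0, alpha=1.0, r_min=0.0)
        assert net.graph["f0"]["f1"]["r"] > 0.5

    def test_independent_features_have_small_correlations(self):
        feats = [f"f{i}" for i in range(10)]
        table, _ = synth.simulate_abundance(feats, [], n_samples=200, depth=10_000, seed=4)
        net = sparcc_network(table, n_permutations=5, seed=0, alpha=1.0, r_min=0.0)
        rs = [abs(d["r"]) for _, _, d in net.graph.edges(data=True)]
        assert np.median(rs) < 0.15

    def test_agrees_with_pearson_on_strong_planted_sign(self):
        feats = [f"f{i}" for i in range(12)]
        table, _ = synth.simulate_abundance(
            feats, [(("f0", "f1"), 0.85)], n_samples=200, depth=10_000, seed=5
        )
        sp = sparcc_network(table, n_permutations=10, seed=0, alpha=1.0, r_min=0.0)
        pe = pearson_network(table, alpha=1.0, r_min=0.0)
        assert sp.graph["f0"]["f1"]["r"] > 0
        assert pe.graph["f0"]["f1"]["r"] > 0

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            sparcc_network(_table([[1, 2, 3, 4]] * 3))

    def test_seed_recorded_in_metadata(self):
        feats = [f"f{i}" for i in range(5)]
        table, _ = synth.simulate_abundance(feats, [], n_samples=20, depth=2000, seed=6)
        net = sparcc_network(table, n_permutations=5, seed=42)
        assert net.metadata["seed"] == 42


def _manual_network(edges, nodes):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, r in edges:
        g.add_edge(u, v, r=r, p_raw=0.001, q_fdr=0.01)
    return CooccurrenceNetwork(g, "pearson", 0.05, 0.4)


class TestNormalizedLinkCounts:
    def test_complete_positive_graph_within_category(self):
        nodes = ["a", "b", "c"]
        edges = [("a", "b", 0.9), ("a", "c", 0.9), ("b", "c", 0.9)]
        lcm = normalized_link_counts(_manual_network(edges, nodes), {n: "X" for n in nodes})
        assert lcm.values.loc["X", "X"] == pytest.approx(1.0)

    def test_no_edges_all_zero(self):
        lcm = normalized_link_counts(
            _manual_network([], ["a", "b", "c"]), {"a": "X", "b": "X", "c": "Y"}
        )
        assert (lcm.values.to_numpy() == 0).all()

    def test_bipartite_normalization(self):
        nodes = ["a1", "a2", "b1", "b2", "b3"]
        cats = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
        edges = [("a1", "b1", 0.8), ("a1", "b2", 0.8), ("a2", "b3", 0.8)]
        lcm = normalized_link_counts(_manual_network(edges, nodes), cats)
        assert lcm.values.loc["A", "B"] == pytest.approx(3 / 6)
        assert lcm.values.loc["B", "A"] == pytest.approx(3 / 6)

    def test_negative_edges_not_counted(self):
        nodes = ["a", "b"]
        lcm = normalized_link_counts(
            _manual_network([("a", "b", -0.9)], nodes), {"a": "X", "b": "X"}
        )
        assert lcm.values.loc["X", "X"] == 0.0

    def test_uncategorized_node_rejected(self):
        with pytest.raises(ValueError):
            normalized_link_counts(_manual_network([], ["a", "b"]), {"a": "X"})


class TestExport:
    def test_round_trip(self, tmp_path):
        net = _manual_network(
            [("a", "b", 0.5), ("b", "c", 0.7), ("a", "c", 0.9)], ["a", "b", "c"]
        )
        edge_path, node_path = export_network(net, tmp_path, category_map={"a": "X", "b": "X", "c": "Y"})
        again = read_network(edge_path)
        assert set(map(frozenset, again.graph.edges)) == set(map(frozenset, net.graph.edges))

    def test_empty_network_header_only(self, tmp_path):
        net = _manual_network([], ["a"])
        edge_path, node_path = export_network(net, tmp_path)
        assert pd.read_csv(edge_path, sep="\t").empty
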