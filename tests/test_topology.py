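"""Centralities and strongest-edge selection, checked against brute-force
path enumeration and a dense eigensolver."""

import itertools

import numpy as np
import pandas as pd
import pytest

from anaerobenet.confidence import ConfidentNetwork
from anaerobenet.topology import (
    betweenness,
    centrality_report,
    eigenvector_centrality,
    export_graph,
    in_degree,
    influential_report,
    out_degree,
    top_k_edges,
)


def net_from_edges(edges, taxa=None):
    df = pd.DataFrame(edges, columns=["source", "target", "strength"])
    df["sign"] = np.where(df["strength"] >= 0, "activation", "repression")
    df["P"] = 1.0
    if taxa is None:
        taxa = sorted(set(df["source"]) | set(df["target"]))
    return ConfidentNetwork(edges=df, taxa=list(taxa))


def random_digraph(n, density, seed):
    rng = np.random.default_rng(seed)
    edges = [
        (f"n{i}", f"n{j}", float(rng.normal()))
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < density
    ]
    return net_from_edges(edges, taxa=[f"n{i}" for i in range(n)]) if edges else None


def brute_force_betweenness(network):
    """All-pairs shortest-path enumeration, independent of networkx."""
    nodes = list(network.taxa)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for row in network.edges.itertuples():
        adj[idx[row.source], idx[row.target]] = True
    INF = float("inf")
    dist = np.where(adj, 1.0, INF)
    np.fill_diagonal(dist, 0.0)
    # Floyd-Warshall distances
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    # count shortest paths by DP over increasing distance
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted(range(n), key=lambda v: dist[s, v])
        for v in order:
            if v == s or dist[s, v] == INF:
                continue
            sigma[s, v] = sum(
                sigma[s, u] for u in range(n) if adj[u, v] and dist[s, u] + 1 == dist[s, v]
            )
    btw = dict.fromkeys(nodes, 0.0)
    for s, t, v in itertools.product(range(n), repeat=3):
        if len({s, t, v}) == 3 and dist[s, t] < INF and sigma[s, t] > 0:
            if dist[s, v] + dist[v, t] == dist[s, t]:
                btw[nodes[v]] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


class TestTopKEdges:
    def test_k_one_takes_max_absolute_strength(self):
        net = net_from_edges([("a", "b", 3.0), ("b", "c", -5.0)])
        top = top_k_edges(net, 1)
        assert top.edges.iloc[0]["strength"] == -5.0

    def test_ties_broken_lexicographically(self):
        net = net_from_edges([("b", "c", 1.0), ("a", "b", 1.0), ("a", "c", 1.0)])
        top = top_k_edges(net, 2)
        assert list(zip(top.edges["source"], top.edges["target"])) == [
            ("a", "b"),
            ("a", "c"),
        ]

    def test_k_beyond_edge_count_is_identity(self):
        net = net_from_edges([("a", "b", 1.0), ("b", "c", 2.0)])
        assert top_k_edges(net, 100).n_edges == 2

    def test_idempotent(self):
        net = random_digraph(6, 0.5, 50)
        once = top_k_edges(net, 5)
        twice = top_k_edges(once, 5)
        pd.testing.assert_frame_equal(once.edges, twice.edges)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            top_k_edges(net_from_edges([("a", "b", 1.0)]), 0)


class TestDegrees:
    def test_star_in_degree(self):
        net = net_from_edges([(f"s{i}", "hub", 1.0) for i in range(5)])
        assert in_degree(net)["hub"] == 5
        assert out_degree(net)["hub"] == 0

    def test_empty_graph_all_zero(self):
        net = net_from_edges([("a", "b", 1.0)], taxa=["a", "b", "c"])
        net = ConfidentNetwork(edges=net.edges.iloc[:0], taxa=["a", "b", "c"])
        assert set(in_degree(net).values()) == {0}

    def test_matches_adjacency_column_sums(self):
        net = random_digraph(10, 0.3, 51)
        nodes = net.taxa
        idx = {n: i for i, n in enumerate(nodes)}
        adj = np.zeros((10, 10))
        for row in net.edges.itertuples():
            adj[idx[row.source], idx[row.target]] = 1
        indeg = in_degree(net)
        np.testing.assert_array_equal(
            [indeg[n] for n in nodes], adj.sum(axis=0)
        )
        total = sum(in_degree(net).values())
        assert total == sum(out_degree(net).values()) == net.n_edges


class TestBetweenness:
    def test_path_graph(self):
        net = net_from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        btw = betweenness(net)
        assert btw["b"] == pytest.approx(1.0)
        assert btw["a"] == btw["c"] == 0.0

    def test_complete_digraph_all_zero(self):
        nodes = list("abcd")
        net = net_from_edges(
            [(u, v, 1.0) for u in nodes for v in nodes if u != v]
        )
        assert set(betweenness(net).values()) == {0.0}

    @pytest.mark.parametrize("n, density, seed", [
        (4, 0.4, 60), (5, 0.3, 61), (5, 0.6, 62), (6, 0.3, 63), (6, 0.5, 64), (6, 0.8, 65),
    ])
    def test_matches_brute_force_enumeration(self, n, density, seed):
        net = random_digraph(n, density, seed)
        if net is None:
            pytest.skip("degenerate draw with no edges")
        got = betweenness(net)
        want = brute_force_betweenness(net)
        for node in net.taxa:
            assert got[node] == pytest.approx(want[node], abs=1e-9), node


class TestEigenvector:
    def test_complete_graph_uniform(self):
        nodes = list("abcd")
        net = net_from_edges([(u, v, 1.0) for u in nodes for v in nodes if u != v])
        cent = eigenvector_centrality(net)
        assert all(v == pytest.approx(1.0, abs=1e-6) for v in cent.values())

    def test_star_hub_dominates(self):
        net = net_from_edges([(f"s{i}", "hub", 1.0) for i in range(4)])
        cent = eigenvector_centrality(net)
        assert cent["hub"] == pytest.approx(1.0)
        leaves = [cent[f"s{i}"] for i in range(4)]
        assert all(v < 1 for v in leaves)
        assert np.ptp(leaves) < 1e-9

    @pytest.mark.parametrize("n, seed", [(6, 70), (8, 71), (12, 72)])
    def test_matches_dense_eigensolver(self, n, seed):
        # connected graph: ring + random chords
        rng = np.random.default_rng(seed)
        edges = [(f"n{i}", f"n{(i + 1) % n}", 1.0) for i in range(n)]
        for _ in range(n):
            i, j = rng.integers(0, n, 2)
            if i != j:
                edges.append((f"n{i}", f"n{j}", 1.0))
        net = net_from_edges(edges, taxa=[f"n{i}" for i in range(n)])
        got = eigenvector_centrality(net, tol=1e-12)
        # oracle: dominant eigenvector of the symmetrized adjacency
        idx = {t: i for i, t in enumerate(net.taxa)}
        A = np.zeros((n, n))
        for row in net.edges.itertuples():
            A[idx[row.source], idx[row.target]] = 1
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        vals, vecs = np.linalg.eigh(A)
        v = np.abs(vecs[:, -1])
        v /= v.max()
        for t in net.taxa:
            assert got[t] == pytest.approx(v[idx[t]], abs=1e-6)

    def test_empty_graph_rejected(self):
        net = net_from_edges([("a", "b", 1.0)], taxa=["a", "b"])
        empty = ConfidentNetwork(edges=net.edges.iloc[:0], taxa=[])
        with pytest.raises(ValueError):
            eigenvector_centrality(empty)


class TestInfluentialReport:
    def test_ranked_by_eigenvector_desc(self):
        net = net_from_edges(
            [("a", "hub", 1.0), ("b", "hub", 1.0), ("c", "hub", 1.0), ("a", "b", 1.0)]
        )
        rep = influential_report(net)
        assert rep.iloc[0]["taxon"] == "hub"
        assert (np.diff(rep["eigenvector"]) <= 1e-12).all()

    def test_single_node(self):
        net = ConfidentNetwork(
            edges=pd.DataFrame(columns=["source", "target", "strength", "sign", "P"]),
            taxa=["only"],
        )
        rep = influential_report(net)
        assert rep.iloc[0]["taxon"] == "only"

    def test_low_out_degree_flag(self):
        net = net_from_edges(
            [("a", "sink", 1.0), ("b", "sink", 1.0), ("a", "b", 1.0), ("a", "c", 1.0)]
        )
        rep = influential_report(net).set_index("taxon")
        assert bool(rep.loc["sink", "low_out_degree"])
        assert not bool(rep.loc["a", "low_out_degree"])

    def test_permutation_invariance(self):
        net = random_digraph(7, 0.4, 80)
        perm = list(np.random.default_rng(81).permutation(net.taxa))
        shuffled = ConfidentNetwork(
            edges=net.edges.sample(frac=1, random_state=0).reset_index(drop=True),
            taxa=perm,
        )
        a = influential_report(net).reset_index(drop=True)
        b = influential_report(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestExport:
    def test_writes_graphml_and_gexf(self, tmp_path):
        net = net_from_edges([("a", "b", 1.5), ("b", "c", -0.5)])
        export_graph(net, tmp_path / "g.graphml", "graphml")
        export_graph(net, tmp_path / "g.gexf", "gexf")
        assert (tmp_path / "g.graphml").stat().st_size > 0
        assert (tmp_path / "g.gexf").stat().st_size > 0
        with pytest.raises(ValueError):
            export_graph(net, tmp_path / "g.x", "dot")
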