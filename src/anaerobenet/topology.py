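"""Topological analysis of the confident interaction network.

Edges are directional effects (source taxon -> affected taxon), so
in-degree counts the number of taxa influencing a node and betweenness is
computed on the directed, unweighted graph (raw Brandes pair counts with
fractional credit for tied shortest paths). Eigenvector centrality is
computed on the symmetrized graph — "importance by association" does not
depend on effect direction — and rescaled so the most central node scores
1. "Strongest" edges are those with largest absolute strength; signs
encode activation vs repression, not magnitude.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .confidence import ConfidentNetwork

__all__ = [
    "top_k_edges",
    "in_degree",
    "out_degree",
    "betweenness",
    "eigenvector_centrality",
    "centrality_report",
    "influential_report",
    "export_graph",
]


def top_k_edges(network: ConfidentNetwork, k: int) -> ConfidentNetwork:
    """Sub-network of the k largest-|strength| edges.

    Ties in |strength| are broken lexicographically by (source, target) so
    the selection is deterministic; k beyond the edge count returns all
    edges.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    edges = network.edges.copy()
    edges["_mag"] = edges["strength"].abs()
    edges = edges.sort_values(
        by=["_mag", "source", "target"], ascending=[False, True, True]
    ).drop(columns="_mag")
    return ConfidentNetwork(
        edges=edges.head(k).reset_index(drop=True),
        taxa=list(network.taxa),
        condition=network.condition,
    )


def in_degree(network: ConfidentNetwork) -> dict[str, int]:
    g = network.to_networkx()
    return dict(g.in_degree())


def out_degree(network: ConfidentNetwork) -> dict[str, int]:
    g = network.to_networkx()
    return dict(g.out_degree())


def betweenness(network: ConfidentNetwork) -> dict[str, float]:
    """Directed, unweighted betweenness as raw shortest-path pair counts."""
    g = network.to_networkx()
    return nx.betweenness_centrality(g, normalized=False)


def eigenvector_centrality(
    network: ConfidentNetwork, max_iter: int = 1000, tol: float = 1e-9
) -> dict[str, float]:
    """Power-iteration eigenvector centrality on the symmetrized graph.

    Normalized so the maximum score is 1. Nodes outside the dominant
    connected component may score ~0; an empty graph raises.
    """
    g = network.to_networkx().to_undirected()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        # no connections: centrality degenerates to uniform
        return {n: 1.0 for n in g.nodes}
    try:
        cent = nx.eigenvector_centrality(g, max_iter=max_iter, tol=tol)
    except nx.PowerIterationFailedConvergence:
        raise RuntimeError(
            f"power iteration did not converge within max_iter={max_iter}"
        ) from None
    top = max(cent.values())
    return {n: v / top for n, v in cent.items()}


def centrality_report(
    network: ConfidentNetwork, max_iter: int = 1000, tol: float = 1e-9
) -> pd.DataFrame:
    """All centralities per node: in/out degree, betweenness, eigenvector."""
    indeg = in_degree(network)
    outdeg = out_degree(network)
    btw = betweenness(network)
    eig = eigenvector_centrality(network, max_iter=max_iter, tol=tol)
    return pd.DataFrame(
        {
            "taxon": list(indeg),
            "in_degree": [indeg[n] for n in indeg],
            "out_degree": [outdeg[n] for n in indeg],
            "betweenness": [btw[n] for n in indeg],
            "eigenvector": [eig[n] for n in indeg],
        }
    )


def influential_report(
    network: ConfidentNetwork, top_n: int | None = None, low_out_cutoff: int = 1
) -> pd.DataFrame:
    """Taxa ranked by eigenvector centrality (ties by label).

    ``low_out_degree`` flags taxa that receive influence but rarely exert
    it (out-degree <= cutoff) — the nodes a network sketch would mark with
    an asterisk.
    """
    if top_n is not None and top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    rep = centrality_report(network)
    rep["low_out_degree"] = rep["out_degree"] <= low_out_cutoff
    rep = rep.sort_values(
        by=["eigenvector", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)
    rep.insert(0, "rank", rep.index + 1)
    return rep if top_n is None else rep.head(top_n)


def export_graph(network: ConfidentNetwork, path, fmt: str = "graphml") -> None:
    """Write the network with centralities as node attributes (GEXF/GraphML)."""
    g = network.to_networkx()
    if g.number_of_nodes():
        rep = centrality_report(network).set_index("taxon")
        nx.set_node_attributes(g, rep["in_degree"].to_dict(), "in_degree")
        nx.set_node_attributes(g, rep["out_degree"].to_dict(), "out_degree")
        nx.set_node_attributes(g, rep["betweenness"].to_dict(), "betweenness")
        nx.set_node_attributes(g, rep["eigenvector"].to_dict(), "eigenvector")
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'graphml' or 'gexf')")
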