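"""Hub-gene scoring inside a network module.

A module's weight matrix is binarised by keeping the strongest
within-module edges (top quantile, ties inclusive); on the largest
connected component each node gets four topology metrics — degree,
betweenness centrality, mean shortest-path length and local clustering
coefficient. A node scores one point for membership in the top 20% by
connectivity, top 20% by betweenness, bottom 20% by path length and
bottom 20% by clustering coefficient (boundary ties included); a score of
2 or more marks a hub.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_module_graph", "graph_metrics", "hub_scores",
           "overlap_with_candidates"]


def build_module_graph(weights: pd.DataFrame, module_genes,
                       edge_quantile: float = 0.9) -> tuple[nx.Graph, list[str]]:
    """Binarise a module's weight matrix at an edge-weight quantile.

    Keeps within-module edges with weight >= the `edge_quantile` quantile
    of all within-module pairwise weights (so tied boundary edges are all
    kept), then restricts to the largest connected component. Returns the
    graph and the list of genes dropped as isolated/minor-component nodes.
    """
    genes = list(module_genes)
    if len(genes) < 5:
        raise ValueError("module too small for hub analysis (need >= 5 genes)")
    if not 0 < edge_quantile < 1:
        raise ValueError("edge_quantile must be in (0, 1)")
    w = weights.loc[genes, genes].to_numpy(float)
    iu = np.triu_indices(len(genes), k=1)
    vals = w[iu]
    threshold = np.quantile(vals, edge_quantile)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, j, v in zip(iu[0], iu[1], vals):
        if v >= threshold:
            g.add_edge(genes[i], genes[j], weight=float(v))
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    if not components or len(components[0]) < 3:
        raise ValueError("thresholded module graph is (nearly) empty; "
                         "lower edge_quantile")
    main = components[0]
    dropped = [n for n in genes if n not in main]
    return g.subgraph(main).copy(), dropped


def graph_metrics(g: nx.Graph) -> pd.DataFrame:
    """Degree, unnormalised betweenness, mean shortest-path length and local
    clustering coefficient per node of a connected graph."""
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    if not nx.is_connected(g):
        raise ValueError("graph must be connected (prune components first)")
    betweenness = nx.betweenness_centrality(g, normalized=False)
    clustering = nx.clustering(g)  # 0 for degree < 2
    n = g.number_of_nodes()
    rows = {}
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        mean_len = sum(lengths.values()) / (n - 1)
        rows[node] = {
            "connectivity": g.degree(node),
            "betweenness": betweenness[node],
            "path_length": mean_len,
            "clustering_coefficient": clustering[node],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _boundary_set(values: pd.Series, frac: float, highest: bool) -> set:
    """Top (or bottom) `frac` of nodes by value, inclusive of boundary ties."""
    k = math.ceil(frac * len(values))
    ordered = values.sort_values(ascending=not highest, kind="stable")
    boundary = ordered.iloc[k - 1]
    if highest:
        return set(values.index[values >= boundary])
    return set(values.index[values <= boundary])


def hub_scores(metrics: pd.DataFrame, top_frac: float = 0.2) -> pd.DataFrame:
    """Score each node by the four hub criteria; score >= 2 marks a hub.

    Criteria: highest connectivity, highest betweenness, lowest mean path
    length, lowest clustering coefficient — each the top `top_frac` of
    nodes with boundary ties included. The returned frame is sorted for
    reporting by descending score then descending connectivity.
    """
    if len(metrics) < 5:
        raise ValueError("need at least 5 nodes to rank hub criteria")
    criteria = [
        ("connectivity", True),
        ("betweenness", True),
        ("path_length", False),
        ("clustering_coefficient", False),
    ]
    score = pd.Series(0, index=metrics.index)
    for col, highest in criteria:
        members = _boundary_set(metrics[col], top_frac, highest)
        score[list(members)] += 1
    out = metrics.copy()
    out["score"] = score
    out["is_hub"] = score >= 2
    if (score == 4).all():
        warnings.warn("all nodes tie on every hub criterion (degenerate metrics)",
                      UserWarning)
    return out.sort_values(["score", "connectivity"], ascending=False, kind="stable")


def overlap_with_candidates(hubs: pd.DataFrame, candidate_genes,
                            probe_to_gene: pd.Series | None = None) -> list[str]:
    """Hub gene symbols that also appear in a prior candidate list.

    When `probe_to_gene` is given, hub row ids are probes and are mapped to
    symbols first; otherwise the ids are taken as gene symbols directly.
    """
    hub_ids = list(hubs.index[hubs["is_hub"]])
    if probe_to_gene is not None:
        symbols = {probe_to_gene.get(p) for p in hub_ids} - {None}
    else:
        symbols = set(hub_ids)
    return sorted(symbols & set(candidate_genes))
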