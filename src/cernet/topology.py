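"""Centrality analysis of the ceRNA network and hub-centered modules.

Three classical centralities rank nodes of the (unweighted, undirected)
bipartite lncRNA-mRNA network:

* degree K — number of incident edges;
* betweenness B_i — sum over ordered pairs s != i != t of the fraction
  of shortest s-t paths through i, normalized by (n-1)(n-2) with n the
  total node count of the analyzed network;
* closeness C_i — reciprocal of the summed shortest-path distances
  from i to all nodes reachable from it (no component-size
  correction; disconnected networks are therefore comparable only
  within a component).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


def degree(net: nx.Graph) -> dict[str, int]:
    """Per-node degree K."""
    return dict(net.degree())


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Normalized betweenness centrality.

    Equivalent to the ordered-pair sum with 1/((n-1)(n-2))
    normalization; pairs with no connecting path contribute 0. For
    n < 3 the normalization is undefined and all-zero values are
    returned with a warning.
    """
    n = net.number_of_nodes()
    if n < 3:
        if n:
            warnings.warn("betweenness undefined for n < 3; returning zeros")
        return {v: 0.0 for v in net.nodes}
    return nx.betweenness_centrality(net, normalized=True)


def closeness(net: nx.Graph) -> dict[str, float]:
    """Closeness C_i = 1 / sum of distances to reachable nodes.

    Isolated nodes get 0 by convention (warned).
    """
    out: dict[str, float] = {}
    isolated = []
    for v in net.nodes:
        dists = nx.single_source_shortest_path_length(net, v)
        total = sum(d for u, d in dists.items() if u != v)
        if total == 0:
            out[v] = 0.0
            isolated.append(v)
        else:
            out[v] = 1.0 / total
    if isolated:
        warnings.warn(f"{len(isolated)} isolated node(s) assigned closeness 0")
    return out


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node, one row per node."""
    deg = degree(net)
    btw = betweenness(net)
    clo = closeness(net)
    df = pd.DataFrame({
        "node": sorted(net.nodes),
    })
    df["degree"] = [deg[v] for v in df["node"]]
    df["betweenness"] = [btw[v] for v in df["node"]]
    df["closeness"] = [clo[v] for v in df["node"]]
    if "kind" in next(iter(net.nodes(data=True)), (None, {}))[1]:
        df["kind"] = [net.nodes[v].get("kind") for v in df["node"]]
    return df.set_index("node")


def top_k(table: pd.DataFrame, metric: str, k: int = 10) -> list[str]:
    """Top-k node ids by a centrality column, ties broken lexicographically."""
    if k <= 0:
        return []
    df = table.reset_index() if "node" not in table.columns else table.copy()
    ranked = df.sort_values([metric, "node"], ascending=[False, True],
                            kind="mergesort")
    return list(ranked["node"].head(k))


def intersect_top_k(table: pd.DataFrame, k: int = 10) -> set[str]:
    """Nodes present in the top-k of degree, betweenness and closeness."""
    sets = [set(top_k(table, m, k)) for m in ("degree", "betweenness", "closeness")]
    return sets[0] & sets[1] & sets[2]


def first_neighbors(net: nx.Graph, node: str) -> set[str]:
    """Direct neighbors of a node (empty for isolated nodes)."""
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    return set(net.neighbors(node))


def extract_cerna_module(triple: nx.Graph, lncrna: str,
                         mrnas: Iterable[str]) -> nx.Graph:
    """Induced ceRNA-module subnetwork of the global triple network.

    Nodes: the lncRNA, the given mRNAs, and every miRNA adjacent in the
    triple network to the lncRNA AND to at least one of the mRNAs.
    """
    mrnas = list(mrnas)
    for g in (lncrna, *mrnas):
        if g not in triple:
            raise KeyError(f"node {g!r} not in triple network")
    lnc_mirnas = set(triple.neighbors(lncrna))
    mediators = {mi for mi in lnc_mirnas
                 if any(triple.has_edge(mi, mr) for mr in mrnas)}
    return triple.subgraph({lncrna, *mrnas, *mediators}).copy()
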