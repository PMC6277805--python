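"""Weighted graph measures: clustering, path length, degree and betweenness.

Segregation is measured by the weighted clustering coefficient

    Ci = 1 / (Si (Ki - 1)) * sum_{(j,k)} (Wij + Wik)

where the sum runs over neighbor pairs (j, k) of node i that are themselves
connected (closed triangles), Si is node strength and Ki binary degree — the
Barrat normalization.  Integration is the characteristic path length li,
the mean over other nodes of the minimum-cost path with edge traversal cost
1 / weight (strong coupling = short functional distance, the Brain
Connectivity Toolbox convention).  Hubness is measured by binary degree
centrality and by betweenness centrality BC(v) = sum over pairs s != v != t
of sigma_st(v) / sigma_st on the same 1/weight shortest paths; BC is
rescaled by its nodewise mean so values are comparable across graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .graph_build import BrainGraph

__all__ = [
    "NodeMetrics",
    "GlobalMetrics",
    "node_clustering",
    "clustering_coefficients",
    "mean_clustering",
    "node_path_lengths",
    "node_path_length",
    "char_path_length",
    "degree_centrality",
    "betweenness_centrality",
    "compute_node_metrics",
    "compute_global_metrics",
]


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node measures on one brain graph."""

    node: int
    label: str
    Ci: float
    Si: float
    Ki: int
    li: float
    DC: int
    BC_raw: float
    BC_norm: float


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network segregation (C) and integration (L) at one density."""

    C: float
    L: float
    sparsity: float


def _cost_matrix(bg: BrainGraph) -> np.ndarray:
    w = bg.weight_matrix()
    with np.errstate(divide="ignore"):
        cost = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return cost


def node_clustering(bg: BrainGraph, v: int, variant: str = "barrat") -> float:
    """Weighted clustering coefficient of node ``v``.

    ``variant='barrat'`` (default) implements the closed-triangle sum above;
    ``variant='onnela'`` delegates to the geometric-mean formulation for
    sensitivity analyses.
    """
    if variant == "onnela":
        return float(nx.clustering(bg.graph, v, weight="weight"))
    if variant != "barrat":
        raise ValueError(f"unknown clustering variant {variant!r}")
    g = bg.graph
    neighbors = sorted(g[v])
    k = len(neighbors)
    if k <= 1:
        return 0.0
    s = sum(g[v][j]["weight"] for j in neighbors)
    total = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            j, kk = neighbors[a], neighbors[b]
            if g.has_edge(j, kk):
                total += g[v][j]["weight"] + g[v][kk]["weight"]
    return total / (s * (k - 1))


def clustering_coefficients(bg: BrainGraph, variant: str = "barrat") -> np.ndarray:
    return np.array([node_clustering(bg, v, variant) for v in range(bg.n_nodes)])


def mean_clustering(bg: BrainGraph, variant: str = "barrat") -> float:
    """Network clustering coefficient C: nodewise mean of Ci."""
    return float(clustering_coefficients(bg, variant).mean())


def node_path_lengths(bg: BrainGraph) -> np.ndarray:
    """li for every node: mean shortest-path cost (1/weight) to all others."""
    n = bg.n_nodes
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    dist = dijkstra(csr_array(_cost_matrix(bg)), directed=False)
    if not np.all(np.isfinite(dist)):
        raise ValueError("graph is disconnected")
    return dist.sum(axis=1) / (n - 1)


def node_path_length(bg: BrainGraph, v: int) -> float:
    return float(node_path_lengths(bg)[v])


def char_path_length(bg: BrainGraph) -> float:
    """Characteristic path length L: nodewise mean of li."""
    return float(node_path_lengths(bg).mean())


def degree_centrality(bg: BrainGraph) -> np.ndarray:
    """Binary degree of every node (count of suprathreshold edges)."""
    return np.array([bg.graph.degree(v) for v in range(bg.n_nodes)], dtype=int)


def betweenness_centrality(bg: BrainGraph, normalize: bool = True) -> np.ndarray:
    """Betweenness on 1/weight shortest paths, summed over unordered pairs.

    With ``normalize`` each raw value is divided by the nodewise mean raw
    betweenness; a mean of zero (e.g. a complete graph) maps everything to 0.
    """
    for i, j in bg.graph.edges:
        bg.graph[i][j]["cost"] = 1.0 / bg.graph[i][j]["weight"]
    raw_map = nx.betweenness_centrality(bg.graph, normalized=False, weight="cost")
    raw = np.array([raw_map[v] for v in range(bg.n_nodes)])
    if not normalize:
        return raw
    mean = raw.mean()
    if mean == 0:
        return np.zeros_like(raw)
    return raw / mean


def compute_node_metrics(
    bg: BrainGraph, clustering_variant: str = "barrat"
) -> list[NodeMetrics]:
    ci = clustering_coefficients(bg, clustering_variant)
    li = node_path_lengths(bg)
    dc = degree_centrality(bg)
    bc_raw = betweenness_centrality(bg, normalize=False)
    mean_bc = bc_raw.mean()
    bc_norm = bc_raw / mean_bc if mean_bc > 0 else np.zeros_like(bc_raw)
    return [
        NodeMetrics(
            node=v,
            label=bg.labels[v],
            Ci=float(ci[v]),
            Si=float(sum(d["weight"] for _, _, d in bg.graph.edges(v, data=True))),
            Ki=int(dc[v]),
            li=float(li[v]),
            DC=int(dc[v]),
            BC_raw=float(bc_raw[v]),
            BC_norm=float(bc_norm[v]),
        )
        for v in range(bg.n_nodes)
    ]


def compute_global_metrics(
    bg: BrainGraph, clustering_variant: str = "barrat"
) -> GlobalMetrics:
    return GlobalMetrics(
        C=mean_clustering(bg, clustering_variant),
        L=char_path_length(bg),
        sparsity=bg.sparsity,
    )
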