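"""Sparse connected brain graphs: MST backbone plus proportional thresholding.

Proportional thresholding alone can disconnect weakly coupled regions, so the
graph is anchored on the maximum spanning tree (the N-1 strongest edges that
still reach every node) and the remaining budget at the requested density is
filled with the highest-weight non-tree edges.  Every graph is therefore
connected at every density, and graphs are nested across densities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = ["BrainGraph", "maximum_spanning_tree", "threshold_to_graph", "export_graph"]


def _edge_order_key(item: tuple[tuple[int, int], float]):
    # weight descending, then (i, j) ascending: bit-reproducible across runs
    (i, j), w = item
    return (-w, i, j)


@dataclass(frozen=True)
class BrainGraph:
    """Connected weighted undirected graph at a stated edge density.

    Nodes are 0..N-1 in atlas order; ``labels`` carries the ROI names.
    ``backbone`` is the maximum-spanning-tree edge set that guarantees
    connectedness; ``sparsity`` is the realized edge fraction.
    """

    graph: nx.Graph
    labels: tuple[str, ...]
    sparsity: float
    backbone: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        g = self.graph
        n = g.number_of_nodes()
        if n >= 2 and not nx.is_connected(g):
            raise ValueError("brain graph must be connected")
        if any(i == j for i, j in g.edges):
            raise ValueError("self-loops are not allowed")
        if any(d["weight"] <= 0 for _, _, d in g.edges(data=True)):
            raise ValueError("edge weights must be positive")
        if not self.backbone <= {tuple(sorted(e)) for e in g.edges}:
            raise ValueError("backbone must be a subset of the edge set")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def weight_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=range(self.n_nodes), weight="weight")


def _sorted_edges(values: np.ndarray) -> list[tuple[tuple[int, int], float]]:
    n = values.shape[0]
    edges = [((i, j), float(values[i, j])) for i in range(n) for j in range(i + 1, n)]
    edges.sort(key=_edge_order_key)
    return edges


def maximum_spanning_tree(cm: ConnectivityMatrix) -> list[tuple[int, int, float]]:
    """Maximum spanning tree of the complete weighted graph (Prim's algorithm).

    Zero entries count as weight-0 edges so a tree always exists.  Ties are
    broken by (weight descending, i ascending, j ascending) for deterministic
    output.  Returns N-1 edges as (i, j, weight) with i < j.
    """
    n = cm.n_rois
    if n == 0:
        raise ValueError("empty connectivity matrix")
    values = cm.values
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    tree: list[tuple[int, int, float]] = []
    while len(tree) < n - 1:
        best = None
        best_key = None
        for u in np.flatnonzero(in_tree):
            for v in np.flatnonzero(~in_tree):
                i, j = (u, v) if u < v else (v, u)
                key = (-values[i, j], i, j)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        tree.append((int(i), int(j), float(values[i, j])))
        in_tree[i] = in_tree[j] = True
    tree.sort(key=lambda e: (e[0], e[1]))
    return tree


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def threshold_to_graph(cm: ConnectivityMatrix, s: float) -> BrainGraph:
    """Build the connected graph at edge density ``s``.

    Target edge count E = max(N-1, round(s * N(N-1)/2), half-up).  The MST
    backbone is always included; the remaining E - (N-1) slots are filled
    with the strongest non-tree edges in deterministic order.
    """
    if not 0 < s <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    n = cm.n_rois
    m_possible = n * (n - 1) // 2
    target = max(n - 1, _round_half_up(s * m_possible))

    mst = maximum_spanning_tree(cm)
    mst_pairs = {(i, j) for i, j, _ in mst}

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j, w in mst:
        g.add_edge(i, j, weight=max(w, np.finfo(float).tiny))

    for (i, j), w in _sorted_edges(cm.values):
        if g.number_of_edges() >= target:
            break
        if (i, j) in mst_pairs or w <= 0:
            continue
        g.add_edge(i, j, weight=w)

    realized = g.number_of_edges() / m_possible if m_possible else 0.0
    return BrainGraph(
        graph=g,
        labels=tuple(cm.labels),
        sparsity=float(realized),
        backbone=frozenset(mst_pairs),
    )


def export_graph(bg: BrainGraph, edges_path: str | Path, sidecar_path: str | Path) -> None:
    """Write edge-list CSV (source,target,weight) plus a JSON sidecar."""
    import pandas as pd

    rows = [
        (bg.labels[i], bg.labels[j], d["weight"])
        for i, j, d in sorted(bg.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source_label", "target_label", "weight"]).to_csv(
        edges_path, index=False
    )
    sidecar = {
        "n_nodes": bg.n_nodes,
        "n_edges": bg.n_edges,
        "sparsity": bg.sparsity,
        "backbone": sorted([bg.labels[i], bg.labels[j]] for i, j in bg.backbone),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))
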