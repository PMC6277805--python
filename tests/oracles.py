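"""Independent brute-force oracles used only by the test suite.

Each oracle is deliberately naive (exhaustive enumeration) so that it shares
no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

REL_TOL = 1e-9


def brute_force_mst_weight(weights: np.ndarray) -> float:
    """Maximum spanning-tree weight by enumerating all (N-1)-edge subsets."""
    n = weights.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = -np.inf
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph(subset)
        g.add_nodes_from(range(n))
        if nx.is_connected(g):
            best = max(best, sum(weights[i, j] for i, j in subset))
    return best


def brute_force_shortest_costs(g: nx.Graph) -> np.ndarray:
    """All-pairs minimum path cost (cost = 1/weight) via simple-path listing."""
    n = g.number_of_nodes()
    dist = np.zeros((n, n))
    for s in range(n):
        for t in range(s + 1, n):
            best = np.inf
            for path in nx.all_simple_paths(g, s, t):
                cost = sum(
                    1.0 / g[path[k]][path[k + 1]]["weight"]
                    for k in range(len(path) - 1)
                )
                best = min(best, cost)
            dist[s, t] = dist[t, s] = best
    return dist


def brute_force_betweenness(g: nx.Graph) -> np.ndarray:
    """Raw betweenness by listing every simple path between every pair and
    counting those within relative tolerance of the minimum cost."""
    n = g.number_of_nodes()
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = []
            for path in nx.all_simple_paths(g, s, t):
                cost = sum(
                    1.0 / g[path[k]][path[k + 1]]["weight"]
                    for k in range(len(path) - 1)
                )
                paths.append((cost, path))
            best = min(c for c, _ in paths)
            shortest = [p for c, p in paths if c <= best * (1 + REL_TOL)]
            sigma = len(shortest)
            for path in shortest:
                for v in path[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def enumerate_signed_rank_p(diffs: np.ndarray) -> float:
    """Literal 2^n enumeration of the exact two-sided signed-rank p-value."""
    from scipy.stats import rankdata

    d = diffs[diffs != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for r, sign in zip(ranks, signs) if sign)
            for signs in itertools.product([False, True], repeat=len(d))
        ]
    )
    lower = np.mean(ws <= w_obs + 1e-12)
    upper = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


def random_brain_graph(seed: int):
    """Small random connected weighted graph plus its connectivity matrix."""
    from motorgraph.connectivity import ConnectivityMatrix
    from motorgraph.graph_build import threshold_to_graph

    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    w = rng.uniform(0.2, 2.0, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    cm = ConnectivityMatrix(values=w, labels=tuple(f"R{i}" for i in range(n)))
    s = float(rng.uniform(0.3, 1.0))
    return cm, threshold_to_graph(cm, s)
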