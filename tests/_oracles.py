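"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: exhaustive simple-path enumeration for minimum path
costs, repeated-relaxation (Floyd-Warshall) distance matrices and boolean
transitive closure for centrality.  Nothing here shares code with the
package's Dijkstra/ranking path.
"""

from __future__ import annotations

import numpy as np


def enumerate_min_costs(nodes, cost, min_edges=0):
    """Minimum simple-path cost for every ordered pair by DFS enumeration.

    ``cost`` maps (u, v) -> edge cost.  Returns {(s, t): (min_cost,
    min_edges_on_best)} considering only simple paths with >= ``min_edges``
    edges; pairs with no such path are absent.
    """
    nodes = list(nodes)
    succ = {u: sorted(v for (a, v) in cost if a == u) for u in nodes}
    best: dict[tuple, float] = {}

    def dfs(start, u, visited, acc, n_edges):
        for v in succ[u]:
            if v in visited:
                continue
            c = acc + cost[(u, v)]
            if n_edges + 1 >= min_edges and v != start:
                key = (start, v)
                if key not in best or c < best[key]:
                    best[key] = c
            dfs(start, v, visited | {v}, c, n_edges + 1)

    for s in nodes:
        dfs(s, s, {s}, 0.0, 0)
    return best


def floyd_warshall_distances(nodes, cost):
    """All-pairs shortest-path distance matrix by repeated relaxation."""
    nodes = list(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (u, v), c in cost.items():
        d[idx[u], idx[v]] = min(d[idx[u], idx[v]], c)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return nodes, d


def transitive_closure(nodes, cost):
    """Boolean reachability matrix by iterated boolean matrix product."""
    nodes = list(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for (u, v) in cost:
        adj[idx[u], idx[v]] = True
    reach = adj.copy()
    for _ in range(n):
        new = reach | (reach @ adj)
        if (new == reach).all():
            break
        reach = new
    return nodes, reach


def brute_ripple(nodes, cost):
    """Ripple-centrality vector straight from the definitions.

    Raw closeness = 1 / sum of shortest-path costs to reachable nodes
    (0 for none); raw reachability = reachable-node count.  Closeness is
    max-normalized, reachability divided by N - 1; ripple is the product.
    Degenerate graphs (< 3 nodes) score zero everywhere.
    """
    nodes = list(nodes)
    n = len(nodes)
    if n < 3:
        z = {u: 0.0 for u in nodes}
        return dict(z), dict(z), dict(z)
    _, dmat = floyd_warshall_distances(nodes, cost)
    _, rmat = transitive_closure(nodes, cost)
    raw_c, raw_r = {}, {}
    for i, u in enumerate(nodes):
        reach = [dmat[i, j] for j in range(n) if j != i and rmat[i, j]]
        raw_r[u] = len(reach)
        raw_c[u] = 1.0 / sum(reach) if reach else 0.0
    max_c = max(raw_c.values())
    close = {u: (raw_c[u] / max_c if max_c > 0 else 0.0) for u in nodes}
    reachn = {u: raw_r[u] / (n - 1) for u in nodes}
    ripple = {u: close[u] * reachn[u] for u in nodes}
    return close, reachn, ripple
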