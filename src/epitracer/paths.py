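"""Highest-activity path (HAP) extraction.

For one condition network, computes the minimum-cost (= highest-activity)
path for every ordered pair of reachable nodes, keeps only paths with at
least two edges (single-edge paths carry no ripple information), and
retains the paths whose cost falls inside a percentile threshold of the
ascending cost ranking.

Determinism contract: when several paths tie for the minimum cost of a
pair, the single retained path is the one produced by a Dijkstra whose
priority queue breaks distance ties on node identifier and whose
neighbors are explored in lexicographic order, with predecessors updated
only on strict improvement.  This is seedless and reproducible across
runs and platforms, which the regression and rescaling tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from heapq import heappop, heappush
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .core import ConditionNetwork
from .errors import EpitracerError, ParameterError

__all__ = [
    "ActivePath",
    "HAPSet",
    "all_pairs_highest_activity",
    "percentile_filter",
    "extract_hap_set",
    "write_hap_set",
    "read_hap_set",
]


class ActivePath:
    """An ordered node sequence with its summed edge cost.

    Identity (equality / hashing) is the node sequence alone: two paths
    with the same sequence but different costs — as happens when the same
    route is found in both conditions — compare equal, which is exactly
    the semantics the common-path discard step needs.
    """

    __slots__ = ("nodes", "cost")

    def __init__(self, nodes: tuple[str, ...], cost: float):
        self.nodes = tuple(nodes)
        self.cost = float(cost)

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    def edges(self) -> Iterator[tuple[str, str]]:
        return zip(self.nodes[:-1], self.nodes[1:])

    def __eq__(self, other) -> bool:
        return isinstance(other, ActivePath) and self.nodes == other.nodes

    def __hash__(self) -> int:
        return hash(self.nodes)

    def __repr__(self) -> str:
        return f"ActivePath({'|'.join(self.nodes)}, cost={self.cost:.6g})"


@dataclass
class HAPSet:
    """The retained highest-activity paths for one condition.

    ``paths`` is sorted ascending by (cost, node sequence); ``q`` is the
    percentile that was applied and ``cutoff`` the realized cost cutoff
    (every member's cost is <= cutoff, boundary ties included).
    """

    condition: str
    paths: tuple[ActivePath, ...]
    q: float
    cutoff: float

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self) -> Iterator[ActivePath]:
        return iter(self.paths)

    def __contains__(self, item) -> bool:
        seq = item.nodes if isinstance(item, ActivePath) else tuple(item)
        return seq in self.sequences()

    def sequences(self) -> set[tuple[str, ...]]:
        return {p.nodes for p in self.paths}


# ---------------------------------------------------------------------------
# Deterministic Dijkstra
# ---------------------------------------------------------------------------

def _sorted_adjacency(network: ConditionNetwork) -> dict[str, list[tuple[str, float]]]:
    g = network.graph
    return {
        u: sorted((v, g.edges[u, v]["cost"]) for v in g.successors(u))
        for u in g.nodes
    }


def _dijkstra(adj: dict[str, list[tuple[str, float]]], source: str):
    """Single-source shortest paths with deterministic tie-breaking.

    Returns (dist, pred, hops); hops counts edges on the chosen path.
    Edge costs must be > 0.
    """
    dist: dict[str, float] = {source: 0.0}
    pred: dict[str, str | None] = {source: None}
    hops: dict[str, int] = {source: 0}
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heappop(heap)
        if u in done:
            continue
        done.add(u)
        du_hops = hops[u]
        for v, c in adj[u]:
            nd = d + c
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                hops[v] = du_hops + 1
                heappush(heap, (nd, v))
    return dist, pred, hops


def _reconstruct(pred: dict[str, str | None], target: str) -> tuple[str, ...]:
    seq = [target]
    u = pred[target]
    while u is not None:
        seq.append(u)
        u = pred[u]
    seq.reverse()
    return tuple(seq)


# ---------------------------------------------------------------------------
# All-pairs stage
# ---------------------------------------------------------------------------

def all_pairs_highest_activity(network: ConditionNetwork) -> set[ActivePath]:
    """Minimum-cost path for every ordered reachable pair, >= 2 edges.

    One path per pair (deterministic tie-break); pairs that are direct
    neighbors on their optimal route (single-edge paths) are excluded.
    Returns the empty set when no pair is >= 2 hops apart.
    """
    if network.number_of_nodes() == 0:
        raise EpitracerError("condition network is empty")
    adj = _sorted_adjacency(network)
    out: set[ActivePath] = set()
    for s in sorted(adj):
        dist, pred, hops = _dijkstra(adj, s)
        for t, d in dist.items():
            if t != s and hops[t] >= 2:
                out.add(ActivePath(_reconstruct(pred, t), d))
    return out


def percentile_filter(paths: Iterable[ActivePath], q: float,
                      condition: str = "") -> HAPSet:
    """Retain the paths inside the ``q``-th percentile of ascending cost.

    With ``N`` input paths, ``k = ceil(q/100 * N)`` and the realized
    cutoff is the k-th smallest path cost; every path with cost <= cutoff
    is retained, so boundary ties can push the result above ``k``.
    ``q = 100`` is the identity.
    """
    if not (0 < q <= 100):
        raise ParameterError(f"percentile must lie in (0, 100], got {q}")
    paths = list(paths)
    if not paths:
        raise EpitracerError(
            "no candidate paths: the condition network has no pair of nodes "
            ">= 2 hops apart — check graph connectivity")
    n = len(paths)
    k = math.ceil(q / 100.0 * n)
    costs = np.sort(np.array([p.cost for p in paths]))
    cutoff = float(costs[k - 1])
    kept = sorted((p for p in paths if p.cost <= cutoff),
                  key=lambda p: (p.cost, p.nodes))
    return HAPSet(condition=condition, paths=tuple(kept), q=float(q), cutoff=cutoff)


def extract_hap_set(network: ConditionNetwork, q: float,
                    stream_threshold: int = 400) -> HAPSet:
    """All-pairs stage + percentile filter for one condition.

    For networks above ``stream_threshold`` nodes the O(V^2) path set is
    never materialized: a first sweep collects per-pair costs only, the
    realized cutoff is derived from them, and a second sweep reconstructs
    just the retained paths.  Results are identical to the direct route.
    """
    if network.number_of_nodes() <= stream_threshold:
        return percentile_filter(all_pairs_highest_activity(network), q,
                                 condition=network.condition)
    if not (0 < q <= 100):
        raise ParameterError(f"percentile must lie in (0, 100], got {q}")
    adj = _sorted_adjacency(network)
    sources = sorted(adj)
    # pass 1: costs only
    costs: list[float] = []
    for s in sources:
        dist, _pred, hops = _dijkstra(adj, s)
        costs.extend(d for t, d in dist.items() if t != s and hops[t] >= 2)
    if not costs:
        raise EpitracerError(
            "no candidate paths: the condition network has no pair of nodes "
            ">= 2 hops apart — check graph connectivity")
    n = len(costs)
    k = math.ceil(q / 100.0 * n)
    arr = np.sort(np.asarray(costs))
    cutoff = float(arr[k - 1])
    # pass 2: reconstruct retained paths only
    kept: list[ActivePath] = []
    for s in sources:
        dist, pred, hops = _dijkstra(adj, s)
        for t, d in dist.items():
            if t != s and hops[t] >= 2 and d <= cutoff:
                kept.append(ActivePath(_reconstruct(pred, t), d))
    kept.sort(key=lambda p: (p.cost, p.nodes))
    return HAPSet(condition=network.condition, paths=tuple(kept),
                  q=float(q), cutoff=cutoff)


# ---------------------------------------------------------------------------
# Serialization: condition<TAB>cost<TAB>node1|node2|...
# ---------------------------------------------------------------------------

def write_hap_set(hap_set: HAPSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# percentile={hap_set.q!r}\tcutoff={hap_set.cutoff!r}\n")
        for p in hap_set.paths:
            fh.write(f"{hap_set.condition}\t{p.cost!r}\t{'|'.join(p.nodes)}\n")


def read_hap_set(path) -> HAPSet:
    q = cutoff = None
    condition = ""
    paths: list[ActivePath] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                fields = dict(kv.split("=", 1) for kv in line[1:].strip().split("\t"))
                q = float(fields["percentile"])
                cutoff = float(fields["cutoff"])
                continue
            if not line.strip():
                continue
            condition, cost, seq = line.split("\t")
            paths.append(ActivePath(tuple(seq.split("|")), float(cost)))
    if q is None or cutoff is None:
        raise EpitracerError(f"{path}: missing HAP-set header line")
    return HAPSet(condition=condition, paths=tuple(paths), q=q, cutoff=cutoff)
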