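"""Ripple centrality and epicenter ranking.

A good epicenter is the source of highly active paths (high outward
closeness on the cost-weighted graph) AND can reach a large part of the
network (high outward reachability).  Ripple centrality is the product
of the two factors after normalization — a "logical AND": it is zero
whenever either factor is zero.

Normalization conventions (monotone, hence rank-preserving):

* outward reachability is divided by ``N - 1`` (N = CSHAN node count);
* closeness is divided by the maximum raw closeness over the CSHAN, so
  both factors live in [0, 1] and the product is interpretable.

Closeness is OUTWARD: the reciprocal of the summed shortest-path costs
from ``u`` to every node it can reach (0 if it reaches none).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .cshan import CSHAN
from .errors import EpitracerError
from .paths import _dijkstra, _sorted_adjacency

__all__ = [
    "RippleScores",
    "RankEntry",
    "EpicenterRanking",
    "closeness",
    "outward_reachability",
    "ripple_centrality",
    "get_epicenters",
    "lscc_report",
    "LSCCReport",
    "write_ranking",
]

#: Relative tolerance under which two ripple scores share one rank.
TIE_REL_TOL = 1e-9


@dataclass
class RippleScores:
    """Per-node normalized closeness, outward reachability and their product."""

    condition: str
    closeness: dict[str, float]       # normalized, [0, 1]
    reachability: dict[str, float]    # normalized, [0, 1]
    ripple: dict[str, float]          # product of the two, exactly
    raw_closeness: dict[str, float]
    raw_reachability: dict[str, int]

    def __getitem__(self, node: str) -> float:
        return self.ripple[node]


def _cshan_adjacency(cshan: CSHAN) -> dict[str, list[tuple[str, float]]]:
    g = cshan.graph
    return {u: sorted((v, g.edges[u, v]["cost"]) for v in g.successors(u))
            for u in g.nodes}


def _raw_scores(cshan: CSHAN) -> tuple[dict[str, float], dict[str, int]]:
    adj = _cshan_adjacency(cshan)
    raw_c: dict[str, float] = {}
    raw_r: dict[str, int] = {}
    for u in adj:
        dist, _pred, _hops = _dijkstra(adj, u)
        reach = [d for t, d in dist.items() if t != u]
        raw_r[u] = len(reach)
        raw_c[u] = 1.0 / sum(reach) if reach else 0.0
    return raw_c, raw_r


def closeness(cshan: CSHAN, u: str) -> float:
    """Normalized outward closeness of ``u`` in the CSHAN."""
    return ripple_centrality(cshan).closeness[u]


def outward_reachability(cshan: CSHAN, u: str) -> float:
    """Normalized outward reachability of ``u`` in the CSHAN."""
    return ripple_centrality(cshan).reachability[u]


def ripple_centrality(cshan: CSHAN) -> RippleScores:
    """Score every CSHAN node: normalized closeness x normalized reachability.

    A graph with fewer than 3 nodes cannot arise from paths with >= 2
    edges; such degenerate inputs are handled by scoring every node zero.
    """
    if cshan.number_of_nodes() == 0:
        raise EpitracerError("cannot score an empty CSHAN")
    if cshan.number_of_nodes() < 3:
        z = {u: 0.0 for u in cshan.graph.nodes}
        return RippleScores(condition=cshan.condition, closeness=dict(z),
                            reachability=dict(z), ripple=dict(z),
                            raw_closeness=dict(z),
                            raw_reachability={u: 0 for u in z})
    raw_c, raw_r = _raw_scores(cshan)
    n = cshan.number_of_nodes()
    max_c = max(raw_c.values())
    norm_c = {u: (v / max_c if max_c > 0 else 0.0) for u, v in raw_c.items()}
    norm_r = {u: (v / (n - 1) if n > 1 else 0.0) for u, v in raw_r.items()}
    ripple = {u: norm_c[u] * norm_r[u] for u in raw_c}
    return RippleScores(condition=cshan.condition, closeness=norm_c,
                        reachability=norm_r, ripple=ripple,
                        raw_closeness=raw_c, raw_reachability=raw_r)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass
class RankEntry:
    rank: int
    node: str
    ripple: float
    closeness: float
    reachability: float
    membership: str  # "specific" or "global"


@dataclass
class EpicenterRanking:
    """Competition-ranked node list for one membership class.

    Scores are non-increasing down the list; nodes whose ripple scores
    agree within relative tolerance ``TIE_REL_TOL`` form one tie group
    sharing a rank, and the next rank skips the group size (1, 1, 3, ...).
    """

    condition: str
    membership: str
    entries: list[RankEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def nodes(self) -> list[str]:
        return [e.node for e in self.entries]

    def rank_of(self, node: str) -> int | None:
        for e in self.entries:
            if e.node == node:
                return e.rank
        return None

    def top(self, k: int) -> list[RankEntry]:
        return [e for e in self.entries if e.rank <= k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "rank": e.rank, "gene": e.node, "ripple": e.ripple,
            "closeness": e.closeness, "reachability": e.reachability,
            "membership": e.membership} for e in self.entries])


def _tied(a: float, b: float) -> bool:
    return abs(a - b) <= TIE_REL_TOL * max(abs(a), abs(b))


def _competition_rank(scored: list[tuple[str, float]]) -> list[tuple[int, str, float]]:
    """Competition ranking with near-equal scores grouped.

    ``scored`` must be sorted by descending score (ties by node id).  A
    score joins the current group when it ties the group's FIRST member,
    preventing tolerance chaining across slowly decaying score runs.
    """
    out: list[tuple[int, str, float]] = []
    group_head: float | None = None
    group_rank = 1
    for i, (node, score) in enumerate(scored):
        if group_head is None or not _tied(score, group_head):
            group_head = score
            group_rank = i + 1
        out.append((group_rank, node, score))
    return out


def get_epicenters(cshan_analyzed: CSHAN, cshan_other: CSHAN,
                   top_k: int = 10) -> tuple[EpicenterRanking, EpicenterRanking]:
    """Rank the analyzed CSHAN's nodes and split into two epicenter lists.

    Ripple centrality is computed on ``cshan_analyzed``.  Nodes absent
    from ``cshan_other`` go to the condition-SPECIFIC list; nodes present
    in both CSHANs go to the GLOBAL list (they participate in different
    paths per condition — re-wired hubs).  Each list is ranked separately
    and truncated at rank <= ``top_k``, keeping whole tie groups, so a
    list may hold more than ``top_k`` nodes.
    """
    if cshan_analyzed.number_of_nodes() == 0:
        raise EpitracerError(
            "analyzed CSHAN is empty — consider a larger percentile threshold")
    if top_k < 1:
        raise EpitracerError(f"top_k must be >= 1, got {top_k}")
    scores = ripple_centrality(cshan_analyzed)
    other_nodes = cshan_other.nodes

    def build(nodes: list[str], membership: str) -> EpicenterRanking:
        scored = sorted(((n, scores.ripple[n]) for n in nodes),
                        key=lambda t: (-t[1], t[0]))
        ranked = _competition_rank(scored)
        entries = [RankEntry(rank=r, node=n, ripple=s,
                             closeness=scores.closeness[n],
                             reachability=scores.reachability[n],
                             membership=membership)
                   for r, n, s in ranked if r <= top_k]
        return EpicenterRanking(condition=cshan_analyzed.condition,
                                membership=membership, entries=entries)

    specific = build([n for n in cshan_analyzed.nodes if n not in other_nodes],
                     "specific")
    global_ = build([n for n in cshan_analyzed.nodes if n in other_nodes],
                    "global")
    return specific, global_


# ---------------------------------------------------------------------------
# LSCC reporting
# ---------------------------------------------------------------------------

@dataclass
class LSCCReport:
    """Largest strongly connected component membership of ranked nodes."""

    condition: str
    lscc: set[str]
    lscc_size: int
    graph_size: int
    table: pd.DataFrame  # columns: rank, gene, in_lscc


def lscc_report(cshan: CSHAN, ranking: EpicenterRanking) -> LSCCReport:
    """Annotate each ranked node with LSCC membership.

    Epicenters are empirically found inside the largest strongly connected
    component of the highest-activity network, so its size relative to the
    CSHAN is a useful diagnostic.
    """
    if cshan.number_of_nodes() == 0:
        lscc: set[str] = set()
    else:
        lscc = max(nx.strongly_connected_components(cshan.graph),
                   key=lambda c: (len(c), min(c)))
        if len(lscc) == 1:
            # no nontrivial SCC: still report the singleton as size 1
            lscc = set(lscc)
    table = pd.DataFrame([{
        "rank": e.rank, "gene": e.node, "in_lscc": e.node in lscc and len(lscc) > 1}
        for e in ranking.entries])
    return LSCCReport(condition=cshan.condition, lscc=set(lscc),
                      lscc_size=len(lscc), graph_size=cshan.number_of_nodes(),
                      table=table)


def write_ranking(ranking: EpicenterRanking, path, *,
                  lscc: set[str] | None = None,
                  fold_change_table=None) -> None:
    """Write a ranking as TSV.

    Columns: rank, gene, ripple, closeness, reachability, membership,
    in_lscc, fold_change.  The last two columns are filled when an LSCC
    node set / fold-change table is supplied and left as ``NA`` otherwise.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("rank\tgene\tripple\tcloseness\treachability\t"
                 "membership\tin_lscc\tfold_change\n")
        for e in ranking.entries:
            in_lscc = "NA" if lscc is None else str(e.node in lscc)
            if fold_change_table is not None and e.node in fold_change_table:
                fc = repr(fold_change_table.fold_change(e.node))
            else:
                fc = "NA"
            fh.write(f"{e.rank}\t{e.node}\t{e.ripple!r}\t{e.closeness!r}\t"
                     f"{e.reachability!r}\t{e.membership}\t{in_lscc}\t{fc}\n")
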