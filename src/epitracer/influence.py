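"""Immediate influence zone of an epicenter.

The influence zone is every node within ``hops`` (default 2) unweighted
hops upstream or downstream of an epicenter in a chosen graph — either a
condition-specific highest-activity network or the full condition
network.  The summary table lists the input node first, then one row per
dysregulated gene in the zone (fold change >= cutoff or <= 1/cutoff),
annotated with direction (``down_<epi>`` = reachable FROM the epicenter,
``up_<epi>`` = reaches the epicenter), hop distance, fold change, and in
which highest-activity network(s) the gene occurs.  Genes more than one
hop away also carry the intermediate node(s) of one unweighted shortest
path, each with fold change, significance flag and network label.  A gene
lying both upstream and downstream within range yields one row per
direction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .core import FoldChangeTable, is_significant_fold_change
from .cshan import CSHAN
from .errors import EpitracerError, ParameterError

__all__ = [
    "InfluenceZoneReport",
    "influence_zone",
    "combined_influence_zone",
    "which_network_label",
    "write_influence_report",
    "read_influence_rows",
]

LABEL_PERTURBED = "unique to perturbed CSHAN"
LABEL_CONTROL = "unique to control CSHAN"
LABEL_COMMON = "common to both CSHANs"
LABEL_NONE = "not in any CSHAN"


def which_network_label(node: str, cshan_perturbed: CSHAN | None,
                        cshan_control: CSHAN | None) -> str:
    in_p = cshan_perturbed is not None and node in cshan_perturbed
    in_c = cshan_control is not None and node in cshan_control
    if in_p and in_c:
        return LABEL_COMMON
    if in_p:
        return LABEL_PERTURBED
    if in_c:
        return LABEL_CONTROL
    return LABEL_NONE


@dataclass
class InfluenceZoneReport:
    """Zone graph plus the dysregulation summary rows (fixed column order)."""

    epicenters: tuple[str, ...]
    graph_name: str
    hops: int
    fc_cutoff: float
    zone: nx.DiGraph
    rows: pd.DataFrame
    #: node -> epicenters whose zone contains it (combined reports)
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def epicenter(self) -> str:
        return self.epicenters[0]


def _as_graph(g) -> nx.DiGraph:
    return g.graph if hasattr(g, "graph") and isinstance(g.graph, nx.DiGraph) else g


def _bfs(graph: nx.DiGraph, source: str, max_hops: int, *, reverse: bool):
    """Deterministic BFS: (dist, pred) up to ``max_hops``; neighbors are
    explored in sorted order so tie paths resolve lexicographically."""
    nbrs = graph.predecessors if reverse else graph.successors
    dist = {source: 0}
    pred: dict[str, str | None] = {source: None}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if dist[u] == max_hops:
            continue
        for v in sorted(nbrs(u)):
            if v not in dist:
                dist[v] = dist[u] + 1
                pred[v] = u
                queue.append(v)
    return dist, pred


def _walk(pred: dict[str, str | None], node: str) -> list[str]:
    seq = [node]
    u = pred[node]
    while u is not None:
        seq.append(u)
        u = pred[u]
    seq.reverse()  # from source of the BFS outward
    return seq


def _schema(hops: int) -> list[str]:
    cols = ["Node", "Direction", "Num_hops", "Fold_change", "Which_network"]
    for i in range(1, hops):
        cols += [f"Intermediate_node_{i}", f"Fold_change_{i}",
                 f"Significant_fc_{i}", f"Which_network_{i}"]
    return cols


def _row(node: str, direction: str, num_hops: int, intermediates: Sequence[str],
         fc: FoldChangeTable, cshan_p, cshan_c, hops: int) -> dict:
    row = {
        "Node": node,
        "Direction": direction,
        "Num_hops": num_hops,
        "Fold_change": fc.fold_change(node) if node in fc else float("nan"),
        "Which_network": which_network_label(node, cshan_p, cshan_c),
    }
    for i in range(1, hops):
        if i <= len(intermediates):
            m = intermediates[i - 1]
            mfc = fc.fold_change(m) if m in fc else float("nan")
            row[f"Intermediate_node_{i}"] = m
            row[f"Fold_change_{i}"] = mfc
            row[f"Significant_fc_{i}"] = (
                is_significant_fold_change(mfc, fc.cutoff) if m in fc else False)
            row[f"Which_network_{i}"] = which_network_label(m, cshan_p, cshan_c)
        else:
            row[f"Intermediate_node_{i}"] = ""
            row[f"Fold_change_{i}"] = ""
            row[f"Significant_fc_{i}"] = ""
            row[f"Which_network_{i}"] = ""
    return row


def influence_zone(
    epicenter: str,
    graph,
    fold_change_table: FoldChangeTable,
    *,
    hops: int = 2,
    fc_cutoff: float | None = None,
    cshan_perturbed: CSHAN | None = None,
    cshan_control: CSHAN | None = None,
    augment_from_full: str = "down",
    full_network=None,
    graph_name: str = "graph",
) -> InfluenceZoneReport:
    """Influence zone and dysregulation summary for one epicenter.

    ``graph`` is the graph the zone is taken from (a CSHAN, a condition
    network, or a bare DiGraph).  ``fc_cutoff`` defaults to the cutoff the
    fold-change table was built with.  When ``full_network`` is given,
    dysregulated genes within range in the FULL network are added to the
    zone according to ``augment_from_full`` (``down``/``up``/``both``/
    ``none``; default adds downregulated genes, the usual usage when the
    perturbation is an overexpression).
    """
    if hops < 1:
        raise ParameterError(f"hops must be >= 1, got {hops}")
    cutoff = fold_change_table.cutoff if fc_cutoff is None else fc_cutoff
    if cutoff <= 1:
        raise ParameterError(f"fold-change cutoff must be > 1, got {cutoff}")
    if augment_from_full not in ("down", "up", "both", "none"):
        raise ParameterError(f"augment_from_full must be down/up/both/none, "
                             f"got {augment_from_full!r}")
    g = _as_graph(graph)
    if epicenter not in g:
        containing = []
        for name, other in (("perturbed CSHAN", cshan_perturbed),
                            ("control CSHAN", cshan_control),
                            ("full network", full_network)):
            if other is not None and epicenter in _as_graph(other):
                containing.append(name)
        hint = f"; it is present in: {', '.join(containing)}" if containing else ""
        raise EpitracerError(f"epicenter {epicenter!r} not in {graph_name}{hint}")

    fc = fold_change_table

    def collect(src_graph: nx.DiGraph, directions: Iterable[str]):
        rows = []
        zone_nodes: set[str] = set()
        for direction in directions:
            dist, pred = _bfs(src_graph, epicenter, hops,
                              reverse=(direction == "up"))
            for node in sorted(dist):
                if node == epicenter:
                    continue
                zone_nodes.add(node)
                if node in fc and is_significant_fold_change(
                        fc.fold_change(node), cutoff):
                    walk = _walk(pred, node)  # epicenter .. node (BFS order)
                    intermediates = walk[1:-1]
                    rows.append((direction, dist[node],
                                 _row(node, f"{direction}_{epicenter}",
                                      dist[node], intermediates, fc,
                                      cshan_perturbed, cshan_control, hops)))
        return rows, zone_nodes

    rows, zone_nodes = collect(g, ("down", "up"))
    reported = {(r["Node"], d) for d, _h, r in rows}

    zone_edges: set[tuple[str, str]] = set()
    if full_network is not None and augment_from_full != "none":
        wanted = ("down", "up") if augment_from_full == "both" else (augment_from_full,)
        fg = _as_graph(full_network)
        if epicenter in fg:
            aug_rows, _aug_nodes = collect(fg, ("down", "up"))
            for d, h, r in aug_rows:
                node = r["Node"]
                if (node, d) in reported:
                    continue
                if fc.direction(node) not in wanted:
                    continue
                rows.append((d, h, r))
                reported.add((node, d))
                # splice the connecting path from the full network into the zone
                dist, pred = _bfs(fg, epicenter, hops, reverse=(d == "up"))
                walk = _walk(pred, node)
                zone_nodes.update(walk)
                pairs = list(zip(walk[:-1], walk[1:]))
                if d == "up":  # BFS ran on the reverse graph
                    pairs = [(b, a) for a, b in pairs]
                zone_edges.update(pairs)

    zone = nx.DiGraph()
    zone.add_node(epicenter)
    zone.add_nodes_from(zone_nodes)
    zone.add_edges_from((u, v) for u, v in g.edges
                        if u in zone.nodes and v in zone.nodes)
    zone.add_edges_from(zone_edges)

    rows.sort(key=lambda t: (t[0], t[1], t[2]["Node"]))  # down first, then hops, name
    header = _row(epicenter, "input_node", 0, [], fc,
                  cshan_perturbed, cshan_control, hops)
    table = pd.DataFrame([header] + [r for _d, _h, r in rows],
                         columns=_schema(hops))
    return InfluenceZoneReport(epicenters=(epicenter,), graph_name=graph_name,
                               hops=hops, fc_cutoff=cutoff, zone=zone, rows=table,
                               provenance={n: (epicenter,) for n in zone.nodes})


def combined_influence_zone(
    epicenters: Sequence[str],
    graph,
    fold_change_table: FoldChangeTable,
    *,
    hops: int = 2,
    fc_cutoff: float | None = None,
    cshan_perturbed: CSHAN | None = None,
    cshan_control: CSHAN | None = None,
    augment_from_full: str = "none",
    full_network=None,
    graph_name: str = "graph",
    keep: Iterable[str] | None = None,
) -> InfluenceZoneReport:
    """Union of per-epicenter influence zones with per-node provenance.

    When ``keep`` is given the zone graph is pruned to the keep-list nodes
    plus the minimal connectors: any node on an unweighted shortest path
    (within the combined zone) between two kept nodes is retained.
    """
    if not epicenters:
        raise ParameterError("need at least one epicenter")
    reports = [influence_zone(e, graph, fold_change_table, hops=hops,
                              fc_cutoff=fc_cutoff, cshan_perturbed=cshan_perturbed,
                              cshan_control=cshan_control,
                              augment_from_full=augment_from_full,
                              full_network=full_network, graph_name=graph_name)
               for e in epicenters]
    zone = nx.DiGraph()
    prov: dict[str, set[str]] = {}
    for rep in reports:
        zone.add_nodes_from(rep.zone.nodes)
        zone.add_edges_from(rep.zone.edges)
        for n in rep.zone.nodes:
            prov.setdefault(n, set()).add(rep.epicenter)
    rows = pd.concat([r.rows for r in reports], ignore_index=True)

    if keep is not None:
        kept = set(keep) & set(zone.nodes)
        connectors: set[str] = set(kept)
        for s in sorted(kept):
            dist, pred = _bfs(zone, s, zone.number_of_nodes(), reverse=False)
            for t in sorted(kept):
                if t != s and t in dist:
                    connectors.update(_walk(pred, t))
        zone = zone.subgraph(connectors).copy()
        prov = {n: e for n, e in prov.items() if n in connectors}

    return InfluenceZoneReport(
        epicenters=tuple(epicenters), graph_name=graph_name, hops=hops,
        fc_cutoff=reports[0].fc_cutoff, zone=zone, rows=rows,
        provenance={n: tuple(sorted(e)) for n, e in prov.items()})


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_influence_report(report: InfluenceZoneReport, path) -> None:
    """Write the summary rows as TSV in the fixed column order."""
    cols = _schema(report.hops)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in report.rows.iterrows():
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def read_influence_rows(path) -> pd.DataFrame:
    """Parse a summary TSV back into a DataFrame with typed columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out_rows = []
    inter_cols = [c for c in df.columns if c.startswith("Intermediate_node_")]
    for _, row in df.iterrows():
        rec = {
            "Node": row["Node"],
            "Direction": row["Direction"],
            "Num_hops": int(row["Num_hops"]),
            "Fold_change": float(row["Fold_change"]),
            "Which_network": row["Which_network"],
        }
        for c in inter_cols:
            i = c.rsplit("_", 1)[1]
            if row[c]:
                rec[c] = row[c]
                rec[f"Fold_change_{i}"] = float(row[f"Fold_change_{i}"])
                rec[f"Significant_fc_{i}"] = row[f"Significant_fc_{i}"] == "True"
                rec[f"Which_network_{i}"] = row[f"Which_network_{i}"]
            else:
                rec[c] = ""
                rec[f"Fold_change_{i}"] = ""
                rec[f"Significant_fc_{i}"] = ""
                rec[f"Which_network_{i}"] = ""
        out_rows.append(rec)
    return pd.DataFrame(out_rows, columns=list(df.columns))
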