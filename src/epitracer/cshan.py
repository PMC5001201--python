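"""Condition-specific highest-activity networks (CSHANs).

Paths whose node sequence occurs in both conditions are highly active
regardless of the perturbation and carry no information about it; they
are discarded from both sides.  The edges of the remaining
condition-specific paths induce one subgraph per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .core import ConditionNetwork
from .errors import ConfigurationError, IntegrityError
from .paths import ActivePath, HAPSet

logger = logging.getLogger("epitracer")

__all__ = ["CSHAN", "condition_specific_paths", "induce_cshan", "write_cshan_edges"]


@dataclass
class CSHAN:
    """Edge-induced subgraph of one condition's unique paths.

    ``provenance`` maps each edge to the node sequences of the paths that
    support it; every edge lies on at least one condition-specific path
    and isolated nodes cannot occur by construction.
    """

    condition: str
    graph: nx.DiGraph
    provenance: dict[tuple[str, str], tuple[tuple[str, ...], ...]] = field(repr=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def condition_specific_paths(haps_a: HAPSet, haps_b: HAPSet, *,
                             strict: bool = True) -> tuple[HAPSet, HAPSet]:
    """Discard paths common to both HAP sets (by exact node sequence).

    A path that appears in both conditions is removed from BOTH sides even
    though its costs differ between them.  Both sets must have been
    computed at the same percentile; pass ``strict=False`` to downgrade
    that check to a warning.
    """
    if haps_a.q != haps_b.q:
        msg = (f"HAP sets were filtered at different percentiles "
               f"({haps_a.q} vs {haps_b.q})")
        if strict:
            raise ConfigurationError(msg + "; pass strict=False to override")
        logger.warning("%s; proceeding anyway", msg)
    seqs_a = haps_a.sequences()
    seqs_b = haps_b.sequences()
    unique_a = tuple(p for p in haps_a.paths if p.nodes not in seqs_b)
    unique_b = tuple(p for p in haps_b.paths if p.nodes not in seqs_a)
    return (
        HAPSet(haps_a.condition, unique_a, haps_a.q, haps_a.cutoff),
        HAPSet(haps_b.condition, unique_b, haps_b.q, haps_b.cutoff),
    )


def induce_cshan(paths: Iterable[ActivePath], network: ConditionNetwork,
                 condition: str | None = None) -> CSHAN:
    """Edge-induced subgraph of ``network`` from the given paths.

    Edge costs are inherited from the condition network; each edge records
    how many (and which) paths support it.  A path referencing an edge the
    network does not contain raises :class:`IntegrityError`.
    """
    condition = condition if condition is not None else network.condition
    graph = nx.DiGraph()
    prov: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    for p in paths:
        for u, v in p.edges():
            if not network.graph.has_edge(u, v):
                raise IntegrityError(
                    f"path {'|'.join(p.nodes)} uses edge ({u}, {v}) absent "
                    f"from condition network {network.condition!r}")
            if not graph.has_edge(u, v):
                graph.add_node(u, weight=network.node_weight(u))
                graph.add_node(v, weight=network.node_weight(v))
                graph.add_edge(u, v, cost=network.edge_cost(u, v))
                prov[(u, v)] = []
            prov[(u, v)].append(p.nodes)
    for (u, v), supporting in prov.items():
        graph.edges[u, v]["n_paths"] = len(supporting)
    return CSHAN(condition=condition, graph=graph,
                 provenance={e: tuple(ps) for e, ps in prov.items()})


def write_cshan_edges(cshan: CSHAN, path) -> None:
    """TSV edge list with condition and supporting-path count columns."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("source\ttarget\tcondition\tcost\tn_supporting_paths\n")
        for u, v in sorted(cshan.graph.edges):
            d = cshan.graph.edges[u, v]
            fh.write(f"{u}\t{v}\t{cshan.condition}\t{d['cost']!r}\t{d['n_paths']}\n")
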