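"""Domain types and per-condition weighted-network construction.

The central modelling idea: a directed molecular interaction network is
combined with a per-condition expression profile by weighting each node
with its normalized signal intensity (linear scale, strictly positive)
and assigning each directed edge ``(u, v)`` the cost

    c(u, v) = 1 / sqrt(w_u * w_v)

By mass-action reasoning the activity of an interaction is proportional
to the abundance of its participants, so a highly active interaction
receives a very low cost and minimum-cost paths correspond to
highest-activity paths.

This module provides:

* :class:`BaseNetwork` -- the condition-independent directed graph,
* :class:`ExpressionProfile` -- one condition's gene -> intensity map,
* :class:`ConditionNetwork` -- the weighted graph for one condition,
* :class:`FoldChangeTable` -- perturbed/control intensity ratios,
* readers for TSV edge lists, SIF files and expression tables, and a
  GraphML export helper.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError, EpitracerError, ParameterError, ParseError

logger = logging.getLogger("epitracer")

__all__ = [
    "BaseNetwork",
    "ExpressionProfile",
    "ConditionNetwork",
    "FoldChangeTable",
    "load_base_network",
    "load_sif",
    "load_expression",
    "compute_edge_cost",
    "build_condition_network",
    "fold_changes",
    "is_significant_fold_change",
    "write_graphml",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BaseNetwork:
    """A directed interaction network without condition information.

    Nodes are opaque, case-sensitive gene identifiers (non-empty strings);
    an edge ``u -> v`` is a directed interaction.  Self-loops and duplicate
    directed edges are removed at load time and counted here so callers can
    report them.
    """

    graph: nx.DiGraph
    n_self_loops_dropped: int = 0
    n_duplicate_edges_dropped: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ExpressionProfile:
    """Normalized signal intensities for one condition.

    Intensities are on the LINEAR scale and strictly positive: the
    edge-cost formula takes a square root of their product, so zero or
    negative values are rejected (readers may instead floor them, see
    :func:`load_expression`).
    """

    condition: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, v in self.values.items()
               if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0)]
        if bad:
            raise DomainError(
                f"profile {self.condition!r}: {len(bad)} gene(s) with non-positive "
                f"or non-finite intensity (first: {bad[0]!r}); intensities must be "
                "strictly positive on the linear scale"
            )

    @property
    def genes(self) -> set[str]:
        return set(self.values)

    def __getitem__(self, gene: str) -> float:
        return self.values[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.values

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ConditionNetwork:
    """The base network weighted by one condition's expression profile.

    ``graph`` carries a ``weight`` attribute per node (the signal
    intensity) and a ``cost`` attribute per edge, exactly
    ``1/sqrt(w_u * w_v)``.  Nodes of the base network with no expression
    value are dropped together with their incident edges; the counts are
    recorded for reporting.
    """

    condition: str
    graph: nx.DiGraph
    n_unmapped_nodes_dropped: int = 0
    n_edges_dropped: int = 0

    def node_weight(self, node: str) -> float:
        return self.graph.nodes[node]["weight"]

    def edge_cost(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["cost"]

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class FoldChangeTable:
    """Per-gene fold changes (perturbed / control) with significance flags.

    A gene is significant at cutoff ``c`` when its fold change is >= c or
    <= 1/c; the direction flag is ``"up"`` for fold change >= 1 and
    ``"down"`` otherwise.
    """

    cutoff: float
    table: pd.DataFrame = field(repr=False)  # columns: gene, fold_change, direction, significant

    def __post_init__(self) -> None:
        self._fc = {g: float(v) for g, v in
                    zip(self.table["gene"], self.table["fold_change"])}
        self._sig = {g: bool(v) for g, v in
                     zip(self.table["gene"], self.table["significant"])}
        self._dir = {g: str(v) for g, v in
                     zip(self.table["gene"], self.table["direction"])}

    @property
    def genes(self) -> set[str]:
        return set(self._fc)

    def fold_change(self, gene: str) -> float:
        return self._fc[gene]

    def direction(self, gene: str) -> str:
        return self._dir[gene]

    def significant(self, gene: str) -> bool:
        return bool(self._sig[gene])

    def __contains__(self, gene: str) -> bool:
        return gene in self._fc

    def __len__(self) -> int:
        return len(self._fc)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _iter_lines(source) -> Iterable[tuple[int, str]]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            yield from enumerate(fh, start=1)
    else:  # file-like or iterable of lines
        yield from enumerate(source, start=1)


def load_base_network(source, *, directed: bool = True) -> BaseNetwork:
    """Load a directed network from a TSV edge list.

    Each non-blank, non-comment (``#``) line is
    ``source<TAB>target[<TAB>interaction_type]``.  Self-loops and duplicate
    directed edges are dropped with a logged count; node identifiers must
    be non-empty.

    Raises :class:`ParseError` naming the offending line number for
    malformed lines, and for an input containing no edges at all.
    """
    graph = nx.DiGraph()
    self_loops = 0
    duplicates = 0
    n_edges_seen = 0
    for lineno, raw in _iter_lines(source):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:  # tolerate whitespace-separated files
            parts = line.split()
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ParseError(f"line {lineno}: expected 'source<TAB>target[<TAB>type]', got {line!r}")
        u, v = parts[0].strip(), parts[1].strip()
        label = parts[2].strip() if len(parts) > 2 else None
        n_edges_seen += 1
        if u == v:
            self_loops += 1
            graph.add_node(u)  # the node itself is retained
            continue
        if graph.has_edge(u, v):
            duplicates += 1
            continue
        if label is not None:
            graph.add_edge(u, v, interaction=label)
        else:
            graph.add_edge(u, v)
    if n_edges_seen == 0:
        raise ParseError("empty edge list: no edges found in input")
    if self_loops:
        logger.warning("dropped %d self-loop(s) while loading network", self_loops)
    if duplicates:
        logger.info("dropped %d duplicate directed edge(s)", duplicates)
    return BaseNetwork(graph, n_self_loops_dropped=self_loops,
                       n_duplicate_edges_dropped=duplicates)


def load_sif(source) -> BaseNetwork:
    """Load a network in SIF layout: ``source<TAB>relation<TAB>target``."""
    def reordered():
        for lineno, raw in _iter_lines(source):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"line {lineno}: expected 'source<TAB>relation<TAB>target', got {line!r}")
            yield f"{parts[0].strip()}\t{parts[2].strip()}\t{parts[1].strip()}\n"

    return load_base_network(list(reordered()))


def load_expression(
    source,
    condition: str,
    columns: Sequence[str] | None = None,
    *,
    unlog2: bool = False,
    on_nonpositive: str = "error",
) -> ExpressionProfile:
    """Read an expression profile from a TSV table.

    The table has a header row; column 1 holds gene identifiers and the
    remaining columns hold per-sample intensities.  ``columns`` selects the
    sample columns belonging to ``condition`` (default: all of them);
    replicate columns are collapsed by the arithmetic mean.

    ``unlog2=True`` converts log2 inputs back to the linear scale before
    validation.  ``on_nonpositive`` is ``"error"`` (reject, the default) or
    ``"floor"`` (replace with the smallest positive observed intensity
    times 1e-3).
    """
    df = pd.read_csv(source, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError("expression table needs a gene column plus >=1 sample column")
    gene_col = df.columns[0]
    if columns is None:
        columns = [c for c in df.columns[1:]]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParameterError(f"sample column(s) not in table: {missing}")
    mat = df[list(columns)].astype(float)
    if unlog2:
        mat = np.power(2.0, mat)
    vals = mat.mean(axis=1)  # replicates collapsed by arithmetic mean
    genes = df[gene_col].astype(str)
    if genes.duplicated().any():
        # duplicate probes for one gene: average them too
        vals = vals.groupby(genes).mean()
        genes = pd.Series(vals.index)
        vals = pd.Series(vals.values, index=range(len(vals)))
        genes = genes.reset_index(drop=True)
    values = dict(zip(genes, vals))
    nonpos = {g for g, v in values.items() if not (math.isfinite(v) and v > 0)}
    if nonpos:
        if on_nonpositive == "floor":
            positives = [v for v in values.values() if math.isfinite(v) and v > 0]
            if not positives:
                raise DomainError("no positive intensities in table; cannot floor")
            eps = min(positives) * 1e-3
            logger.warning("floored %d non-positive intensit(ies) to %g", len(nonpos), eps)
            for g in nonpos:
                values[g] = eps
        else:
            raise DomainError(
                f"{len(nonpos)} non-positive intensit(ies) in condition {condition!r} "
                "(pass on_nonpositive='floor' to floor them)")
    return ExpressionProfile(condition=condition, values=values)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def compute_edge_cost(w_u: float, w_v: float) -> float:
    """Cost of a directed interaction between nodes of weight ``w_u``, ``w_v``.

    Defined as ``1/sqrt(w_u * w_v)``: the more abundant the participants,
    the more active the interaction and the lower the cost.  Strictly
    decreasing in each argument; raises :class:`DomainError` for
    non-positive weights.
    """
    if w_u <= 0 or w_v <= 0:
        raise DomainError(f"node weights must be > 0, got ({w_u!r}, {w_v!r})")
    return 1.0 / math.sqrt(w_u * w_v)


def build_condition_network(base: BaseNetwork, expr: ExpressionProfile) -> ConditionNetwork:
    """Map an expression profile onto the base network.

    Nodes without an expression value are dropped with their incident
    edges (no imputation); every retained edge gets its cost from
    :func:`compute_edge_cost`.  Raises :class:`EpitracerError` when the
    profile shares no gene with the network.
    """
    mapped = [n for n in base.graph.nodes if n in expr]
    if not mapped:
        raise EpitracerError(
            f"no overlap between expression genes of condition {expr.condition!r} "
            "and network nodes — check identifier conventions")
    graph = nx.DiGraph()
    for n in mapped:
        graph.add_node(n, weight=float(expr[n]))
    kept_edges = 0
    for u, v in base.graph.edges:
        if u in expr and v in expr:
            graph.add_edge(u, v, cost=compute_edge_cost(expr[u], expr[v]))
            kept_edges += 1
    dropped_nodes = base.number_of_nodes() - len(mapped)
    dropped_edges = base.number_of_edges() - kept_edges
    if dropped_nodes:
        logger.info("condition %s: dropped %d unmapped node(s) and %d incident edge(s)",
                    expr.condition, dropped_nodes, dropped_edges)
    return ConditionNetwork(condition=expr.condition, graph=graph,
                            n_unmapped_nodes_dropped=dropped_nodes,
                            n_edges_dropped=dropped_edges)


def is_significant_fold_change(fc: float, cutoff: float) -> bool:
    """True iff ``fc >= cutoff`` or ``fc <= 1/cutoff`` (cutoff > 1)."""
    if cutoff <= 1:
        raise ParameterError(f"fold-change cutoff must be > 1, got {cutoff}")
    return fc >= cutoff or fc <= 1.0 / cutoff


def fold_changes(control: ExpressionProfile, perturbed: ExpressionProfile,
                 cutoff: float = 2.0) -> FoldChangeTable:
    """Per-gene fold change perturbed/control on the shared gene set."""
    if cutoff <= 1:
        raise ParameterError(f"fold-change cutoff must be > 1, got {cutoff}")
    shared = sorted(control.genes & perturbed.genes)
    if not shared:
        raise EpitracerError("control and perturbed profiles share no genes")
    fc = np.array([perturbed[g] / control[g] for g in shared])
    table = pd.DataFrame({
        "gene": shared,
        "fold_change": fc,
        "direction": np.where(fc >= 1.0, "up", "down"),
        "significant": (fc >= cutoff) | (fc <= 1.0 / cutoff),
    })
    return FoldChangeTable(cutoff=cutoff, table=table)


def write_graphml(graph: nx.DiGraph, path) -> None:
    """Export any constructed graph to GraphML."""
    nx.write_graphml(graph, path)
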