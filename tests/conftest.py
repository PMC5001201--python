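import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from epitracer.core import BaseNetwork, ConditionNetwork, compute_edge_cost
from epitracer.cshan import CSHAN
from epitracer.synthetic import generate_case

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


def make_condition_network(edges, weights=None, condition="test") -> ConditionNetwork:
    """Condition network from an edge list; node weights default to 1."""
    g = nx.DiGraph()
    nodes = {n for e in edges for n in e}
    weights = weights or {}
    for n in nodes:
        g.add_node(n, weight=float(weights.get(n, 1.0)))
    for u, v in edges:
        g.add_edge(u, v, cost=compute_edge_cost(
            weights.get(u, 1.0), weights.get(v, 1.0)))
    return ConditionNetwork(condition=condition, graph=g)


def make_cshan(cost_edges, condition="x") -> CSHAN:
    """CSHAN-shaped object from {(u, v): cost} (provenance left empty)."""
    g = nx.DiGraph()
    for (u, v), c in cost_edges.items():
        g.add_edge(u, v, cost=float(c), n_paths=1)
    return CSHAN(condition=condition, graph=g, provenance={})


def random_cost_graph(rng: np.random.Generator, n: int, p: float = 0.3):
    """Random directed weighted graph as ({(u,v): cost}, node list)."""
    nodes = [f"n{i}" for i in range(n)]
    cost = {}
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                cost[(u, v)] = float(rng.uniform(0.1, 2.0))
    return cost, nodes


def random_condition_network(rng: np.random.Generator, n: int,
                             p: float = 0.25, condition="rand") -> ConditionNetwork:
    """Condition network with log-normal node weights and random edges."""
    nodes = [f"n{i:03d}" for i in range(n)]
    weights = {u: float(np.exp(rng.normal(2.0, 0.8))) for u in nodes}
    edges = [(u, v) for u in nodes for v in nodes if u != v and rng.random() < p]
    return make_condition_network(edges, weights, condition)


@pytest.fixture(scope="session")
def default_case():
    """The reference synthetic planted-epicenter case (all defaults, seed 42)."""
    return generate_case()


@pytest.fixture(scope="session")
def small_case():
    """A smaller synthetic case for fast end-to-end tests."""
    return generate_case(n_nodes=80, seed=7)
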