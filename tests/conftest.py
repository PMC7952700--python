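"""Shared fixtures and brute-force reference helpers for the suite."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prynt import DPSet, PPINetwork

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_net(edges, nodes=(), score=950):
    """Directed network from (u, v) pairs or (u, v, score) triples."""
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    for edge in edges:
        u, v, *rest = edge
        graph.add_edge(u, v, score=rest[0] if rest else score,
                       contextual=False)
    return PPINetwork(graph=graph)


def random_net(n, p, rng, score=950):
    """Erdos-Renyi directed network on n labelled nodes."""
    graph = nx.DiGraph()
    names = [f"N{i:02d}" for i in range(n)]
    graph.add_nodes_from(names)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    for i, j in zip(*np.nonzero(mask)):
        graph.add_edge(names[i], names[j], score=score, contextual=False)
    return PPINetwork(graph=graph)


def random_seed_set(net, rng, k=None):
    nodes = sorted(net.nodes)
    k = k or int(rng.integers(1, min(4, len(nodes)) + 1))
    members = rng.choice(nodes, size=k, replace=False).tolist()
    return DPSet(dataset_name="fixture", members=frozenset(members))


def brute_force_maximal_cliques(graph: nx.Graph, min_size: int):
    """Exhaustive subset enumeration; only viable for tiny graphs."""
    nodes = sorted(graph.nodes)
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(a, b)
                   for a, b in itertools.combinations(subset, 2)):
                cliques.append(frozenset(subset))
    return {c for c in cliques if not any(c < d for d in cliques)}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
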