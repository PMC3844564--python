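import networkx as nx
import numpy as np
import pytest

from ppi_impact.graph_io import InteractionEdge, InteractionNetwork, build_network


def network_from_pairs(pairs, with_pmids=True):
    edges = []
    for i, (a, b) in enumerate(pairs):
        pmids = {f"pm{i}"} if with_pmids else set()
        edges.append(InteractionEdge(a, b, frozenset(pmids)))
    return build_network(edges)


def random_network(rng: np.random.Generator, n: int, p: float) -> InteractionNetwork:
    """Erdos-Renyi network with at least one edge, labelled nodes n0..n{n-1}."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() >= 1:
            break
    return network_from_pairs((f"n{a}", f"n{b}") for a, b in g.edges)


@pytest.fixture
def path3():
    """A - B - C."""
    return network_from_pairs([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle():
    return network_from_pairs([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4():
    """Hub H with leaves L1..L3."""
    return network_from_pairs([("H", "L1"), ("H", "L2"), ("H", "L3")])


@pytest.fixture
def diamond():
    """A-B, A-C, B-D, C-D: two equal shortest A-D paths."""
    return network_from_pairs([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])
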