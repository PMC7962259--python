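"""Shared test fixtures: tiny hand-built ontologies and random DAGs."""

import networkx as nx
import numpy as np
import pytest

from chemont.ontology import OntologyGraph


def build_graph(edges, smiles=None, extra_nodes=()):
    """Construct an OntologyGraph from (child, parent) pairs.

    ``smiles`` maps term id -> SMILES annotation.
    """
    g = nx.DiGraph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    for node, s in (smiles or {}).items():
        g.nodes[node]["smiles"] = s
    for node in g.nodes:
        g.nodes[node].setdefault("name", node)
    return OntologyGraph(graph=g)


def random_dag(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.15):
    """A random DAG with child -> parent edges (i -> j only for i > j)."""
    g = nx.DiGraph()
    g.add_nodes_from(f"N{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(i):
            if rng.random() < edge_prob:
                g.add_edge(f"N{i}", f"N{j}")
    for node in g.nodes:
        g.nodes[node]["name"] = node
    return OntologyGraph(graph=g)


@pytest.fixture
def chain_graph():
    """A <- B <- C with a SMILES annotation on the leaf C."""
    return build_graph([("B", "A"), ("C", "B")], smiles={"C": "CCO"})


@pytest.fixture
def diamond_graph():
    """A <- {B, C} <- D: two paths from leaf D up to root A."""
    return build_graph([("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])
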