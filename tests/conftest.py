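import networkx as nx
import pytest

from funcsum.types import FunctionalCluster, OntologyDag


def make_network(edges, nodes=()):
    """Graph from (a, b, weight) triples plus optional isolated nodes."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, w in edges:
        g.add_edge(a, b, weight=float(w))
    return g


def make_dag(parent_edges, nodes=(), namespace="biological_process"):
    """OntologyDag from (child, parent) pairs; all edges is_a."""
    g = nx.DiGraph()
    for n in nodes:
        g.add_node(n, name=n, namespace=namespace)
    for child, parent in parent_edges:
        for n in (child, parent):
            if n not in g:
                g.add_node(n, name=n, namespace=namespace)
        g.add_edge(child, parent, relation="is_a")
    return OntologyDag(g)


def make_cluster(term, members, edges=(), psi=None, cost=None):
    return FunctionalCluster(
        term=term,
        members=frozenset(members),
        induced_edges=tuple((min(a, b), max(a, b), float(w)) for a, b, w in edges),
        psi=psi,
        cost=cost,
    )


@pytest.fixture
def chain_dag():
    """root -> t1 -> t2 (t2 most specific)."""
    return make_dag([("t2", "t1"), ("t1", "root")])


@pytest.fixture
def diamond_dag():
    """Two paths from 'bottom' up to 'top' via 'left' and 'right'."""
    return make_dag(
        [
            ("bottom", "left"),
            ("bottom", "right"),
            ("left", "top"),
            ("right", "top"),
        ]
    )
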