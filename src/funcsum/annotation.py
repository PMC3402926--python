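"""Annotation propagation and candidate cluster induction.

A protein annotated with a GO term is implicitly annotated with every
ancestor of that term (the true-path rule), so each protein carries a sparse
binary term association vector closed under DAG ancestry. Every term then
induces a candidate functional cluster: the subgraph of the interaction
network spanned by the proteins carrying that term.
"""

from __future__ import annotations

import logging

import networkx as nx

from .types import FunctionalCluster, OntologyDag, RawAssociations

logger = logging.getLogger(__name__)


def topological_sort(dag: OntologyDag) -> list[str]:
    """Deterministic topological order of the DAG, parents before children.

    Ties (terms with no ordering constraint between them) are broken
    lexicographically by term id, so the order is a function of the DAG
    alone. Raises ``ValueError`` on a cyclic graph.
    """
    dag.validate()
    # edges run child -> parent; reverse so parents come out first
    return list(nx.lexicographical_topological_sort(dag.graph.reverse(copy=False)))


def propagate_annotations(
    dag: OntologyDag,
    raw: RawAssociations,
    network: nx.Graph,
) -> dict[str, set[str]]:
    """Propagate raw annotations up the DAG into term association vectors.

    Returns a map vertex → set of terms (the sparse binary vector Δ_v):
    for each direct annotation (v, t), v carries t and every ancestor of t
    reachable via the retained relations. Every network vertex gets an
    entry; vertices with no annotation get an empty set. Associations for
    proteins absent from the network, or with terms unknown to the DAG,
    are dropped with a logged warning.
    """
    vectors: dict[str, set[str]] = {v: set() for v in network.nodes}
    # cache ancestor closures per term; annotation lists repeat terms heavily
    closure: dict[str, set[str]] = {}
    unknown_terms = 0
    unknown_proteins = 0
    for protein, term in raw:
        if term not in dag:
            unknown_terms += 1
            continue
        if protein not in vectors:
            unknown_proteins += 1
            continue
        if term not in closure:
            closure[term] = {term} | dag.ancestors(term)
        vectors[protein] |= closure[term]
    if unknown_terms:
        logger.warning("dropped %d association(s) with unknown terms", unknown_terms)
    if unknown_proteins:
        logger.warning(
            "ignored %d association(s) for proteins not in the network",
            unknown_proteins,
        )
    return vectors


def induce_clusters(
    network: nx.Graph,
    vectors: dict[str, set[str]],
    term_order: list[str],
    min_size: int = 2,
    max_size_fraction: float = 1.0,
) -> list[FunctionalCluster]:
    """Build the candidate pool S_Δ: one functional cluster per term.

    A term u induces the cluster of all vertices v with u in Δ_v, together
    with the network edges internal to that vertex set. Clusters smaller
    than *min_size* or larger than ``max_size_fraction * |V|`` are filtered
    out. The pool is returned in *term_order*; two terms with identical
    extents both stay in the pool. Raises ``ValueError`` if the pool comes
    out empty.
    """
    n_vertices = network.number_of_nodes()
    max_size = max_size_fraction * n_vertices

    members_by_term: dict[str, set[str]] = {}
    for vertex, terms in vectors.items():
        for term in terms:
            members_by_term.setdefault(term, set()).add(vertex)

    pool: list[FunctionalCluster] = []
    for term in term_order:
        members = members_by_term.get(term)
        if members is None or len(members) < min_size or len(members) > max_size:
            continue
        subgraph = network.subgraph(members)
        induced = tuple(
            sorted(
                (min(a, b), max(a, b), float(d.get("weight", 1.0)))
                for a, b, d in subgraph.edges(data=True)
            )
        )
        pool.append(
            FunctionalCluster(term=term, members=frozenset(members), induced_edges=induced)
        )
    if not pool:
        raise ValueError(
            "candidate pool is empty; relax min_size/max_size_fraction or "
            "check that annotations overlap the network"
        )
    return pool
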