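"""Core domain types shared across the package.

The central objects are:

* :class:`OntologyDag` — a Gene Ontology DAG with child→parent edges.
* :class:`RawAssociations` — protein→term annotations before propagation.
* :class:`FunctionalCluster` — the subgraph induced by all proteins carrying
  a given term (after true-path propagation up the DAG).
* :class:`SummaryGraph` — the functional summary graph: the selected clusters
  plus the significantly associated cluster pairs.

Protein interaction networks are plain :class:`networkx.Graph` objects with a
``weight`` attribute on every edge; no wrapper type is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx

__all__ = [
    "OntologyDag",
    "RawAssociations",
    "FunctionalCluster",
    "ScoringParams",
    "BudgetLedger",
    "SelectionRecord",
    "AssociationTest",
    "SummaryGraph",
]


@dataclass
class OntologyDag:
    """A Gene Ontology DAG.

    ``graph`` is a directed graph whose edges point child → parent and carry
    a ``relation`` attribute (e.g. ``is_a``, ``part_of``). Node data may hold
    ``name`` and ``namespace`` (BP/MF/CC).
    """

    graph: nx.DiGraph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def parents(self, term: str) -> Iterator[str]:
        """Direct parents of *term* via retained relations."""
        return self.graph.successors(term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from *term* by following child→parent edges."""
        return nx.descendants(self.graph, term)

    def validate(self) -> None:
        """Raise ``ValueError`` naming one cycle if the graph is not acyclic."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"ontology graph contains a cycle: {path}")


@dataclass
class RawAssociations:
    """Un-propagated (protein, term) annotation pairs.

    ``pairs`` preserves input order; ``evidence`` entries may be ``None`` for
    sources that carry no evidence code (plain two-column TSV).
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)
    evidence: list[str | None] = field(default_factory=list)

    def add(self, protein: str, term: str, evidence: str | None = None) -> None:
        self.pairs.append((protein, term))
        self.evidence.append(evidence)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    @property
    def proteins(self) -> set[str]:
        return {p for p, _ in self.pairs}


@dataclass
class FunctionalCluster:
    """The subgraph of the interaction network induced by all proteins
    annotated (post-propagation) with ``term``.

    ``psi`` is the structural information value (ratio association: total
    induced edge weight over cluster size) and ``cost`` the size-deviation
    cost; both are filled in by the scoring stage and are ``None`` until then.
    """

    term: str
    members: frozenset[str]
    induced_edges: tuple[tuple[str, str, float], ...]
    psi: float | None = None
    cost: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"FunctionalCluster(term={self.term!r}, size={self.size}, "
            f"edges={len(self.induced_edges)}, psi={self.psi}, cost={self.cost})"
        )


@dataclass(frozen=True)
class ScoringParams:
    """User-facing knobs of the profit model.

    k
        number of clusters in the summary (summary granularity).
    b
        per-protein information budget; caps the total structural
        information any one protein can contribute across clusters.
    d
        redundancy decay in [0, 10]; after a protein is covered its
        remaining budget is multiplied by d/10, so d=0 makes re-covering
        a protein worthless and d=10 never penalizes overlap beyond b.
    beta
        significance cutoff for inter-cluster association edges, applied
        with Bonferroni correction over all cluster pairs.
    """

    k: int
    b: float = 3.0
    d: float = 0.0
    beta: float = 0.01

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if not 0 <= self.d <= 10:
            raise ValueError(f"d must be in [0, 10], got {self.d}")
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")


@dataclass
class BudgetLedger:
    """Remaining per-protein information budget across greedy iterations."""

    budgets: dict[str, float]
    total_profit: float = 0.0

    @classmethod
    def fresh(cls, proteins, b: float) -> "BudgetLedger":
        return cls(budgets={p: float(b) for p in proteins})

    def copy(self) -> "BudgetLedger":
        return BudgetLedger(dict(self.budgets), self.total_profit)


@dataclass(frozen=True)
class SelectionRecord:
    """One greedy iteration: which cluster was chosen and at what net profit."""

    iteration: int
    term: str
    profit: float
    size: int


@dataclass(frozen=True)
class AssociationTest:
    """Binomial significance test of one cluster pair.

    ``oc`` is the observed inter-cluster interaction count, ``n`` the number
    of Bernoulli trials (product of the cluster sizes) and ``p_value`` the
    inclusive upper tail P(X >= oc) under the background interaction rate.
    """

    term_u: str
    term_v: str
    oc: int
    n: int
    p_value: float
    significant: bool


@dataclass
class SummaryGraph:
    """A functional summary graph.

    ``clusters`` are in selection (α) order. ``edges`` holds only the
    significant pairs; ``tests`` records every pair tested, so the full
    evidence table can be audited or written out.
    """

    clusters: list[FunctionalCluster]
    edges: list[AssociationTest]
    tests: list[AssociationTest]
    params: ScoringParams | None = None
    threshold: float | None = None
    trace: list[SelectionRecord] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return [c.term for c in self.clusters]

    def cluster(self, term: str) -> FunctionalCluster:
        for c in self.clusters:
            if c.term == term:
                return c
        raise KeyError(term)

    def __len__(self) -> int:
        return len(self.clusters)
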