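"""Readers and writers for the formats the tool touches.

Networks come in as whitespace/tab-separated edge lists or SIF; ontologies as
OBO (parsed with :mod:`obonet`); annotations as GAF 2.x or two-column TSV.
Summaries go out as GraphML plus TSV tables. Identifiers are opaque,
case-sensitive strings throughout.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .types import AssociationTest, OntologyDag, RawAssociations, SummaryGraph

logger = logging.getLogger(__name__)

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def read_network(
    path: str | os.PathLike,
    format: str = "tsv",
    default_weight: float = 1.0,
) -> nx.Graph:
    """Read an undirected weighted interaction network.

    TSV lines are ``protein_a protein_b [weight]``, or a single identifier
    declaring an isolated vertex; SIF lines are
    ``source relation target [target ...]``. The network is undirected, so
    ``(a, b)`` and ``(b, a)`` name the same edge; on duplicates the last
    weight read wins. Self-loops are dropped (their count is logged).

    Raises ``ValueError`` on malformed lines (naming the line number) and on
    an empty network.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown network format: {format!r}")

    graph = nx.Graph()
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:  # isolated vertex (both dialects)
                graph.add_node(fields[0])
                continue
            if format == "tsv":
                pairs, weight = _parse_tsv_edge(fields, lineno, default_weight)
            else:
                pairs, weight = _parse_sif_edge(fields, lineno, default_weight)
            for a, b in pairs:
                if a == b:
                    self_loops += 1
                    graph.add_node(a)
                    continue
                graph.add_edge(a, b, weight=weight)
    if self_loops:
        logger.info("dropped %d self-loop(s) while reading %s", self_loops, path)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"{path}: network is empty")
    return graph


def _parse_tsv_edge(fields, lineno, default_weight):
    if len(fields) == 2:
        return [(fields[0], fields[1])], float(default_weight)
    if len(fields) == 3:
        try:
            weight = float(fields[2])
        except ValueError:
            raise ValueError(
                f"line {lineno}: weight {fields[2]!r} is not a number"
            ) from None
        if weight < 0:
            raise ValueError(f"line {lineno}: negative weight {weight}")
        return [(fields[0], fields[1])], weight
    raise ValueError(
        f"line {lineno}: expected 1-3 fields, got {len(fields)}"
    )


def _parse_sif_edge(fields, lineno, default_weight):
    # SIF: "source relation target [target ...]"
    if len(fields) < 3:
        raise ValueError(
            f"line {lineno}: SIF line needs source, relation and >=1 target"
        )
    source = fields[0]
    return [(source, t) for t in fields[2:]], float(default_weight)


def write_network(graph: nx.Graph, path: str | os.PathLike) -> None:
    """Write a network as a 3-column TSV edge list; isolated vertices are
    written as single-field lines so the vertex set round-trips."""
    with open(path, "w") as fh:
        for a, b, data in graph.edges(data=True):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0)}\n")
        for node in graph.nodes:
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def read_ontology(
    path: str | os.PathLike,
    relations: frozenset[str] | set[str] = DEFAULT_RELATIONS,
) -> OntologyDag:
    """Read an OBO file into an :class:`OntologyDag`.

    Obsolete terms are excluded. Only edges whose relation is in *relations*
    (default ``is_a`` and ``part_of``) are retained; annotation propagation
    follows exactly these edges. Raises ``ValueError`` if the retained graph
    has a cycle.
    """
    multi = obonet.read_obo(path)  # obsolete terms are skipped by obonet
    dag = nx.DiGraph()
    dag.add_nodes_from(multi.nodes(data=True))
    for child, parent, relation in multi.edges(keys=True):
        if relation in relations:
            dag.add_edge(child, parent, relation=relation)
    result = OntologyDag(dag)
    result.validate()
    return result


def write_obo(dag: OntologyDag, path: str | os.PathLike) -> None:
    """Write a minimal OBO 1.2 file round-trippable by :func:`read_ontology`."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: funcsum-synthetic\n")
        for term in sorted(dag.graph.nodes):
            data = dag.graph.nodes[term]
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for _, parent, edata in sorted(dag.graph.out_edges(term, data=True)):
                rel = edata.get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------

def read_associations(
    path: str | os.PathLike,
    format: str = "gaf",
    evidence_include: set[str] | None = None,
) -> RawAssociations:
    """Read protein→term associations from GAF 2.x or a two-column TSV.

    GAF rows whose qualifier contains ``NOT`` are excluded. Evidence codes
    are kept unfiltered unless *evidence_include* lists the codes to keep.
    Raises ``ValueError`` with the line number on rows with too few columns.
    """
    path = Path(path)
    if format not in ("gaf", "tsv"):
        raise ValueError(f"unknown association format: {format!r}")
    assoc = RawAssociations()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if format == "tsv":
                if len(fields) < 2:
                    raise ValueError(
                        f"line {lineno}: expected 2 columns, got {len(fields)}"
                    )
                assoc.add(fields[0], fields[1])
            else:
                if len(fields) < 15:
                    raise ValueError(
                        f"line {lineno}: GAF row has {len(fields)} columns, "
                        "expected >= 15"
                    )
                qualifier, term, evidence = fields[3], fields[4], fields[6]
                if "NOT" in qualifier.split("|"):
                    continue
                if evidence_include is not None and evidence not in evidence_include:
                    continue
                assoc.add(fields[1], term, evidence or None)
    return assoc


GAF_HEADER = "!gaf-version: 2.1\n"
_GAF_TEMPLATE = (
    "DB\t{protein}\t{protein}\t\t{term}\tREF\t{evidence}\t\tP\t\t\t"
    "protein\ttaxon:0\t20120101\tFUNC\t\t"
)


def write_gaf(assoc: RawAssociations, path: str | os.PathLike) -> None:
    """Write associations as GAF 2.1 (protein id in column 2)."""
    with open(path, "w") as fh:
        fh.write(GAF_HEADER)
        for (protein, term), ev in zip(assoc.pairs, assoc.evidence):
            fh.write(
                _GAF_TEMPLATE.format(protein=protein, term=term, evidence=ev or "IEA")
                + "\n"
            )


# ---------------------------------------------------------------------------
# reference groupings
# ---------------------------------------------------------------------------

def read_reference(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a 2-column TSV ``protein<TAB>group`` into group → protein set."""
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"line {lineno}: expected 2 columns, got {len(fields)}"
                )
            groups.setdefault(fields[1], set()).add(fields[0])
    return groups


def write_reference(groups: dict[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for label in sorted(groups):
            for protein in sorted(groups[label]):
                fh.write(f"{protein}\t{label}\n")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summary_to_graphml_graph(
    summary: SummaryGraph, dag: OntologyDag | None = None
) -> nx.Graph:
    """Build the GraphML-ready cluster-level graph of a summary."""
    g = nx.Graph()
    for cluster in summary.clusters:
        g.add_node(
            cluster.term,
            name=dag.name(cluster.term) if dag is not None else cluster.term,
            size=cluster.size,
            psi=float(cluster.psi) if cluster.psi is not None else 0.0,
        )
    for test in summary.edges:
        g.add_edge(test.term_u, test.term_v, p_value=float(test.p_value))
    return g


def tests_to_frame(tests: list[AssociationTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_u": t.term_u,
                "term_v": t.term_v,
                "oc": t.oc,
                "n": t.n,
                "p_value": t.p_value,
                "significant": t.significant,
            }
            for t in tests
        ],
        columns=["term_u", "term_v", "oc", "n", "p_value", "significant"],
    )


def write_summary(
    summary: SummaryGraph,
    out_dir: str | os.PathLike,
    dag: OntologyDag | None = None,
    metrics: dict[str, float] | None = None,
) -> dict[str, Path]:
    """Write a summary: GraphML, membership TSV, pairwise-test TSV and,
    when given, a metrics TSV. Returns the paths written, keyed by kind.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths = {"graphml": out_dir / "summary.graphml"}
    nx.write_graphml(summary_to_graphml_graph(summary, dag), paths["graphml"])

    paths["membership"] = out_dir / "membership.tsv"
    with open(paths["membership"], "w") as fh:
        fh.write("protein\tterm\n")
        for cluster in summary.clusters:
            for protein in sorted(cluster.members):
                fh.write(f"{protein}\t{cluster.term}\n")

    paths["tests"] = out_dir / "pairwise_tests.tsv"
    tests_to_frame(summary.tests).to_csv(paths["tests"], sep="\t", index=False)

    if metrics is not None:
        paths["metrics"] = out_dir / "metrics.tsv"
        pd.DataFrame([metrics]).to_csv(paths["metrics"], sep="\t", index=False)
    return paths
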