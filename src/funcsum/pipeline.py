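"""End-to-end wiring: annotations → candidate pool → greedy selection → FSG."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .annotation import induce_clusters, propagate_annotations, topological_sort
from .core import summarize
from .fsg import build_fsg
from .types import (
    BudgetLedger,
    FunctionalCluster,
    OntologyDag,
    RawAssociations,
    ScoringParams,
    SelectionRecord,
    SummaryGraph,
)


@dataclass
class PipelineResult:
    summary: SummaryGraph
    pool: list[FunctionalCluster]
    vectors: dict[str, set[str]]
    term_order: list[str]
    ledger: BudgetLedger
    trace: list[SelectionRecord]


def run_pipeline(
    network: nx.Graph,
    dag: OntologyDag,
    raw: RawAssociations,
    params: ScoringParams,
    min_size: int = 2,
    max_size_fraction: float = 1.0,
    namespace: str | None = None,
    threshold_form: str = "s2",
) -> PipelineResult:
    """Run the full summarization on in-memory inputs.

    Optionally restricts the candidate pool to one GO namespace
    (``biological_process`` / ``molecular_function`` / ``cellular_component``
    or their BP/MF/CC abbreviations).
    """
    order = topological_sort(dag)
    vectors = propagate_annotations(dag, raw, network)
    if namespace is not None:
        wanted = _expand_namespace(namespace)
        order = [t for t in order if dag.namespace(t) in wanted]
    pool = induce_clusters(
        network, vectors, order, min_size=min_size, max_size_fraction=max_size_fraction
    )
    selected, trace, ledger = summarize(network, pool, params)
    summary = build_fsg(
        selected, network, beta=params.beta, threshold_form=threshold_form
    )
    summary.params = params
    summary.trace = trace
    return PipelineResult(summary, pool, vectors, order, ledger, trace)


_NAMESPACES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


def _expand_namespace(namespace: str) -> set[str]:
    full = _NAMESPACES.get(namespace.upper(), namespace)
    return {full}
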