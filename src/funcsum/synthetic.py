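"""Synthetic annotated networks.

Two generators: a random annotated network (Erdős–Rényi-style edges with
Bernoulli term annotations, used for scaling and invariance checks) and a
planted-module network (disjoint attribute-coherent groups with dense
intra-group wiring, used for recovery experiments with a known ground
truth). All randomness flows through one ``numpy`` generator per call, so a
fixed seed reproduces the fixture byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import OntologyDag, RawAssociations

ROOT_TERM = "GO:0000000"


@dataclass(frozen=True)
class SynthConfig:
    """Random annotated network: every vertex pair interacts with
    ``edge_prob`` and every (vertex, term) pair is annotated with
    ``annotation_prob``, independently.

    ``pair_convention`` selects whether ``edge_prob`` applies to unordered
    vertex pairs (default) or to ordered pairs, in which case the effective
    unordered probability is ``1 - (1 - p)^2``; expected edge counts differ
    by roughly a factor of two between the two readings.
    """

    n_vertices: int
    n_terms: int
    annotation_prob: float = 0.02
    edge_prob: float = 0.0025
    seed: int = 0
    pair_convention: str = "unordered"

    def __post_init__(self) -> None:
        if self.n_vertices < 2:
            raise ValueError("n_vertices must be >= 2")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        for name in ("annotation_prob", "edge_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.pair_convention not in ("unordered", "ordered"):
            raise ValueError(f"unknown pair convention: {self.pair_convention!r}")


@dataclass(frozen=True)
class PlantedConfig:
    """Planted attribute-coherent modules.

    ``n_groups`` disjoint groups of ``group_size`` proteins each; every
    group member carries the group's defining term; intra-group vertex
    pairs interact with ``intra_edge_prob`` and inter-group pairs with
    ``inter_edge_prob``. ``n_background_terms`` extra terms annotate any
    vertex with ``background_annotation_prob``, giving the candidate pool
    incoherent competitors.
    """

    n_groups: int = 5
    group_size: int = 20
    intra_edge_prob: float = 0.3
    inter_edge_prob: float = 0.005
    n_background_terms: int = 10
    background_annotation_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.group_size < 2:
            raise ValueError("need n_groups >= 1 and group_size >= 2")
        if self.intra_edge_prob < self.inter_edge_prob:
            raise ValueError("intra_edge_prob must be >= inter_edge_prob")
        for name in ("intra_edge_prob", "inter_edge_prob", "background_annotation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _flat_dag(terms: list[str], namespace: str = "biological_process") -> OntologyDag:
    """A one-root DAG: every term is an is_a child of a single root."""
    graph = nx.DiGraph()
    graph.add_node(ROOT_TERM, name="root", namespace=namespace)
    for term in terms:
        graph.add_node(term, name=term, namespace=namespace)
        graph.add_edge(term, ROOT_TERM, relation="is_a")
    return OntologyDag(graph)


def _term_ids(count: int, offset: int = 1) -> list[str]:
    return [f"GO:{i + offset:07d}" for i in range(count)]


def generate_random_annotated(
    config: SynthConfig,
) -> tuple[nx.Graph, OntologyDag, RawAssociations, dict[str, float]]:
    """Random annotated network with a flat one-root DAG.

    Returns the network (all edge weights 1.0), the DAG, the raw
    associations and a report with expected and observed edge/annotation
    counts for sanity checks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_vertices
    vertices = [f"p{i:05d}" for i in range(n)]

    if config.pair_convention == "unordered":
        p_edge = config.edge_prob
    else:
        p_edge = 1.0 - (1.0 - config.edge_prob) ** 2

    graph = nx.Graph()
    graph.add_nodes_from(vertices)
    # row-chunked Bernoulli sampling over the upper triangle keeps memory
    # bounded for large n
    chunk = max(1, min(n, int(2e7) // max(n, 1)))
    for start in range(0, n - 1, chunk):
        stop = min(start + chunk, n - 1)
        block = rng.random((stop - start, n))
        for local, i in enumerate(range(start, stop)):
            hits = np.nonzero(block[local, i + 1 :] < p_edge)[0]
            for offset in hits:
                graph.add_edge(vertices[i], vertices[i + 1 + offset], weight=1.0)

    terms = _term_ids(config.n_terms)
    dag = _flat_dag(terms)
    raw = RawAssociations()
    for j, term in enumerate(terms):
        hits = np.nonzero(rng.random(n) < config.annotation_prob)[0]
        for i in hits:
            raw.add(vertices[i], term)

    expected_edges = n * (n - 1) / 2 * p_edge
    report = {
        "expected_edges": expected_edges,
        "observed_edges": float(graph.number_of_edges()),
        "edge_sd": float(np.sqrt(n * (n - 1) / 2 * p_edge * (1 - p_edge))),
        "expected_annotations_per_term": n * config.annotation_prob,
        "observed_annotations": float(len(raw)),
    }
    return graph, dag, raw, report


def generate_planted(
    config: PlantedConfig,
) -> tuple[nx.Graph, OntologyDag, RawAssociations, dict[str, set[str]]]:
    """Planted-module network with ground-truth grouping.

    Group g's proteins are all annotated with g's defining term; background
    terms annotate vertices independently. Returns (network, DAG, raw
    associations, group label -> protein set).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_groups * config.group_size
    vertices = [f"p{i:05d}" for i in range(n)]
    group_of = np.repeat(np.arange(config.n_groups), config.group_size)

    graph = nx.Graph()
    graph.add_nodes_from(vertices)
    for i in range(n):
        probs = np.where(
            group_of[i + 1 :] == group_of[i],
            config.intra_edge_prob,
            config.inter_edge_prob,
        )
        hits = np.nonzero(rng.random(n - i - 1) < probs)[0]
        for offset in hits:
            graph.add_edge(vertices[i], vertices[i + 1 + offset], weight=1.0)

    defining = _term_ids(config.n_groups)
    background = _term_ids(config.n_background_terms, offset=config.n_groups + 1)
    dag = _flat_dag(defining + background)

    raw = RawAssociations()
    groups: dict[str, set[str]] = {}
    for g in range(config.n_groups):
        label = f"group{g}"
        members = {vertices[i] for i in range(n) if group_of[i] == g}
        groups[label] = members
        for protein in sorted(members):
            raw.add(protein, defining[g])
    for term in background:
        hits = np.nonzero(rng.random(n) < config.background_annotation_prob)[0]
        for i in hits:
            raw.add(vertices[i], term)

    return graph, dag, raw, groups
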