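"""Summary-quality metrics.

Coverage and redundancy describe how much of the annotated network a summary
represents and how much its clusters overlap. Summary information content
(SIC) weighs each cluster's structural density by its size and the rarity of
its defining term. Against a gold-standard grouping, precision / recall /
F-measure score cluster purity and group coverage; representative-function
metrics do the same for the single term assigned to each cluster by
hypergeometric over-representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import hypergeom

from .types import FunctionalCluster, SummaryGraph


def coverage(
    summary_clusters: list[FunctionalCluster],
    pool: list[FunctionalCluster],
) -> float:
    """Fraction of pool-covered (annotated) proteins present in the summary."""
    denominator = set().union(*(c.members for c in pool)) if pool else set()
    if not denominator:
        raise ValueError("candidate pool covers no proteins")
    if not summary_clusters:
        return 0.0
    numerator = set().union(*(c.members for c in summary_clusters))
    return len(numerator) / len(denominator)


def redundancy(summary_clusters: list[FunctionalCluster]) -> float:
    """Average number of summary clusters each covered protein belongs to.

    Sum of cluster sizes over the size of their union; equals 1 exactly when
    the clusters are pairwise disjoint.
    """
    if not summary_clusters:
        raise ValueError("summary has no clusters")
    union = set().union(*(c.members for c in summary_clusters))
    if not union:
        raise ValueError("summary covers no proteins")
    return sum(c.size for c in summary_clusters) / len(union)


def sic(
    summary_clusters: list[FunctionalCluster],
    vectors: dict[str, set[str]],
) -> float:
    """Summary information content: sum of -psi * |V(u)| * ln p(V(u)).

    p(V(u)) is the probability that an annotated protein carries term u,
    i.e. |V(u)| over the number of annotated proteins (non-empty vectors).
    Natural log. A cluster covering every annotated protein contributes 0.
    """
    n_annotated = sum(1 for terms in vectors.values() if terms)
    if n_annotated == 0:
        raise ValueError("no annotated proteins")
    total = 0.0
    for cluster in summary_clusters:
        if cluster.size == 0:
            raise ValueError(f"cluster {cluster.term} is empty")
        psi = cluster.psi if cluster.psi is not None else 0.0
        p = cluster.size / n_annotated
        total += -psi * cluster.size * math.log(p)
    return total


@dataclass
class ClusterQuality:
    precision: float
    recall: float
    f_measure: float
    purity: dict[str, float]          # cluster term -> purity
    best_match: dict[str, str]        # cluster term -> best-matching group
    group_recall: dict[str, float]    # group label -> recall


def cluster_quality(
    summary_clusters: list[FunctionalCluster],
    reference: dict[str, set[str]],
) -> ClusterQuality:
    """Precision / recall / F-measure of a clustering against reference groups.

    Each cluster is matched to the group with the largest member overlap
    (ties to the lexicographically smallest label); its purity is the
    fraction of members inside that group. Each group's recall is the
    fraction of the group covered by the union of the clusters matched to
    it; groups matched by no cluster score 0. Precision is the mean purity,
    recall the mean group recall, F their harmonic mean.
    """
    if not reference:
        raise ValueError("reference grouping is empty")
    for label, members in reference.items():
        if not members:
            raise ValueError(f"reference group {label!r} is empty")

    purity: dict[str, float] = {}
    best_match: dict[str, str] = {}
    matched_union: dict[str, set[str]] = {label: set() for label in reference}

    for cluster in summary_clusters:
        best_label = min(
            reference,
            key=lambda label: (-len(cluster.members & reference[label]), label),
        )
        best_match[cluster.term] = best_label
        purity[cluster.term] = (
            len(cluster.members & reference[best_label]) / cluster.size
        )
        matched_union[best_label] |= cluster.members

    group_recall = {
        label: len(matched_union[label] & members) / len(members)
        for label, members in reference.items()
    }

    precision = sum(purity.values()) / len(purity) if purity else 0.0
    recall = sum(group_recall.values()) / len(group_recall)
    if precision + recall > 0:
        f_measure = 2 * precision * recall / (precision + recall)
    else:
        f_measure = 0.0
    return ClusterQuality(precision, recall, f_measure, purity, best_match, group_recall)


def hypergeom_pvalue(overlap: int, universe: int, term_count: int, draws: int) -> float:
    """One-sided over-representation p-value: P(X >= overlap) for a
    hypergeometric draw of *draws* from a universe with *term_count*
    successes."""
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe, term_count, draws))


def representative_function(
    cluster: FunctionalCluster,
    vectors: dict[str, set[str]],
    term_order: list[str],
) -> tuple[str, float] | None:
    """Assign the cluster's representative function by enrichment.

    The universe is the set of annotated proteins; for each term the
    over-representation of the cluster's annotated members among the term's
    carriers is scored hypergeometrically, and the term with the smallest
    p-value wins (ties to the earliest term in *term_order*). Returns
    ``None`` when the cluster has no annotated member.
    """
    universe = {v for v, terms in vectors.items() if terms}
    draws = cluster.members & universe
    if not draws:
        return None

    candidate_terms: set[str] = set()
    for v in draws:
        candidate_terms |= vectors[v]

    term_rank = {t: i for i, t in enumerate(term_order)}
    best: tuple[float, int, str] | None = None
    for term in candidate_terms:
        carriers = sum(1 for v in universe if term in vectors[v])
        overlap = sum(1 for v in draws if term in vectors[v])
        p = hypergeom_pvalue(overlap, len(universe), carriers, len(draws))
        key = (p, term_rank.get(term, len(term_rank)), term)
        if best is None or key < best:
            best = key
    return best[2], best[0]


def representativeness(
    clusters_with_function: list[tuple[FunctionalCluster, str]],
    vectors: dict[str, set[str]],
) -> tuple[float, float]:
    """Representative precision and recall of assigned functions.

    Purity of a cluster is the fraction of its annotated members carrying
    the assigned term (unannotated proteins are left out of consideration).
    Recall of a function is the number of annotated carriers captured by the
    clusters assigned that function, over all its carriers in the network.
    Returns (mean purity, mean per-function recall).
    """
    if not clusters_with_function:
        raise ValueError("no clusters with assigned functions")

    purities = []
    captured: dict[str, int] = {}
    for cluster, term in clusters_with_function:
        annotated = [v for v in cluster.members if vectors.get(v)]
        if not annotated:
            raise ValueError(f"cluster {cluster.term} has no annotated member")
        hits = sum(1 for v in annotated if term in vectors[v])
        purities.append(hits / len(annotated))
        captured[term] = captured.get(term, 0) + hits

    recalls = []
    for term, hits in captured.items():
        carriers = sum(1 for terms in vectors.values() if term in terms)
        recalls.append(hits / carriers if carriers else 0.0)

    return sum(purities) / len(purities), sum(recalls) / len(recalls)


def degree_distribution(
    summary: SummaryGraph, top_m: int = 15
) -> tuple[dict[str, int], list[tuple[int, float]], list[str]]:
    """Cluster degrees in the summary graph, their empirical CDF and hubs.

    Returns (term -> degree, sorted (degree, CDF) points, the *top_m* most
    connected clusters — degree ties broken by term id).
    """
    degrees = {c.term: 0 for c in summary.clusters}
    for test in summary.edges:
        degrees[test.term_u] += 1
        degrees[test.term_v] += 1

    values = sorted(degrees.values())
    n = len(values)
    cdf = [(d, sum(1 for v in values if v <= d) / n) for d in sorted(set(values))]
    hubs = sorted(degrees, key=lambda t: (-degrees[t], t))[:top_m]
    return degrees, cdf, hubs


def metrics_report(
    summary: SummaryGraph,
    pool: list[FunctionalCluster],
    vectors: dict[str, set[str]],
    reference: dict[str, set[str]] | None = None,
) -> dict[str, float]:
    """Assemble the standard metric table for a summary."""
    report = {
        "k": float(len(summary.clusters)),
        "coverage": coverage(summary.clusters, pool),
        "redundancy": redundancy(summary.clusters),
        "sic": sic(summary.clusters, vectors),
        "fsg_edges": float(len(summary.edges)),
    }
    if reference is not None:
        quality = cluster_quality(summary.clusters, reference)
        report["precision"] = quality.precision
        report["recall"] = quality.recall
        report["f_measure"] = quality.f_measure
    return report
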