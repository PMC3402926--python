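"""Functional summary graph assembly: which selected cluster pairs are
significantly associated.

Under the null, any two proteins interact independently with the background
rate p_i = 2|E| / (|V|(|V|-1)). For a cluster pair the |C(u)|*|C(v)| member
pairs are treated as iid Bernoulli trials, so the chance of observing oc or
more inter-cluster interactions is an upper binomial tail. A pair is linked
in the summary when that tail falls below a Bonferroni-corrected cutoff.
"""

from __future__ import annotations

import networkx as nx
from scipy.stats import binom

from .types import AssociationTest, FunctionalCluster, SummaryGraph


def background_probability(network: nx.Graph) -> float:
    """Probability that a uniformly random vertex pair interacts.

    Edge weights are ignored; only the edge count enters the null model.
    """
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("network needs at least 2 vertices")
    return 2.0 * network.number_of_edges() / (n * (n - 1))


def inter_cluster_count(
    cluster_u: FunctionalCluster,
    cluster_v: FunctionalCluster,
    network: nx.Graph,
) -> int:
    """Number of network edges connecting the two clusters.

    An edge {i, j} counts once when one endpoint lies in each cluster; for
    overlapping clusters an edge wholly inside the intersection also counts
    once (both endpoints belong to both clusters).
    """
    if not cluster_u.members or not cluster_v.members:
        raise ValueError("clusters must be non-empty")
    mu, mv = cluster_u.members, cluster_v.members
    count = 0
    for i, j in network.edges:
        if (i in mu and j in mv) or (i in mv and j in mu):
            count += 1
    return count


def association_pvalue(oc: int, n: int, p_i: float) -> float:
    """Inclusive upper binomial tail P(X >= oc) with X ~ Binomial(n, p_i)."""
    if not 0 <= oc <= n:
        raise ValueError(f"oc must be in [0, n]; got oc={oc}, n={n}")
    if not 0.0 <= p_i <= 1.0:
        raise ValueError(f"p_i must be in [0, 1]; got {p_i}")
    if oc == 0:
        return 1.0
    return float(binom.sf(oc - 1, n, p_i))


def bonferroni_threshold(beta: float, n_clusters: int, form: str = "s2") -> float:
    """Corrected significance cutoff for all pairwise cluster tests.

    ``form="s2"`` uses 2*beta/|S|^2 (the approximate correction over
    |S|(|S|-1)/2 tests); ``form="kk1"`` uses the exact 2*beta/(|S|(|S|-1)).
    """
    if form == "s2":
        return 2.0 * beta / n_clusters**2
    if form == "kk1":
        if n_clusters < 2:
            return 2.0 * beta  # no pairs to test; value is moot
        return 2.0 * beta / (n_clusters * (n_clusters - 1))
    raise ValueError(f"unknown threshold form: {form!r}")


def build_fsg(
    selected: list[FunctionalCluster],
    network: nx.Graph,
    beta: float = 0.01,
    threshold_form: str = "s2",
) -> SummaryGraph:
    """Test all cluster pairs and assemble the summary graph.

    Every unordered pair of selected clusters gets an upper-tail binomial
    test of its inter-cluster interaction count; pairs at or below the
    Bonferroni-corrected cutoff become summary edges. All tests, significant
    or not, are kept on the result for auditing.
    """
    if not selected:
        raise ValueError("no clusters selected")
    p_i = background_probability(network)
    threshold = bonferroni_threshold(beta, len(selected), threshold_form)

    tests: list[AssociationTest] = []
    edges: list[AssociationTest] = []
    for a in range(len(selected)):
        for b in range(a + 1, len(selected)):
            cu, cv = selected[a], selected[b]
            oc = inter_cluster_count(cu, cv, network)
            n = cu.size * cv.size
            p = association_pvalue(oc, n, p_i)
            test = AssociationTest(
                term_u=cu.term,
                term_v=cv.term,
                oc=oc,
                n=n,
                p_value=p,
                significant=p <= threshold,
            )
            tests.append(test)
            if test.significant:
                edges.append(test)
    return SummaryGraph(
        clusters=list(selected), edges=edges, tests=tests, threshold=threshold
    )
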