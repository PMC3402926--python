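"""Cluster scoring and greedy summary selection.

Selecting k overlapping clusters that jointly maximize extracted structural
information under per-protein budgets is a variant of budgeted maximum
coverage (NP-hard), so the summary is built greedily: at each iteration the
cluster with the highest net profit against the current budget ledger is
committed and removed from the pool.

Profit model. Each cluster C(u) carries a structural information value
psi = (total induced edge weight) / |C(u)| — the ratio-association density —
and a size-deviation cost c = (|C(u)| - |V|/k)^2 discouraging clusters far
from the expected per-cluster size. Each protein i holds a budget b(i),
initially b. Selecting C(u) earns sum_i min(psi, b(i)) over its members,
minus c; the members' budgets then decay to max(0, (d/10) * (b(i) - psi)),
so d=0 spends a covered protein entirely while d>0 leaves diminishing
returns for re-covering it.
"""

from __future__ import annotations

import logging

import networkx as nx

from .types import (
    BudgetLedger,
    FunctionalCluster,
    ScoringParams,
    SelectionRecord,
)

logger = logging.getLogger(__name__)


def structural_information(cluster: FunctionalCluster) -> float:
    """Ratio-association density: induced edge weight per member.

    Each undirected edge counts once. A cluster with no internal edges has
    psi = 0; with nonnegative weights psi is always >= 0.
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    total = sum(w for _, _, w in cluster.induced_edges)
    return total / len(cluster.members)


def size_deviation_cost(cluster_size: int, n_vertices: int, k: int) -> float:
    """Squared deviation of the cluster size from the expected size |V|/k."""
    if k < 1 or n_vertices < 1:
        raise ValueError("k and |V| must be >= 1")
    expected = n_vertices / k
    return (cluster_size - expected) ** 2


def score_pool(
    pool: list[FunctionalCluster], n_vertices: int, k: int
) -> list[FunctionalCluster]:
    """Fill in psi and cost for every candidate, in place; returns the pool."""
    for cluster in pool:
        cluster.psi = structural_information(cluster)
        cluster.cost = size_deviation_cost(cluster.size, n_vertices, k)
    return pool


def cluster_profit(cluster: FunctionalCluster, ledger: BudgetLedger) -> float:
    """Net profit of selecting *cluster* against the current ledger.

    Each member contributes min(psi, remaining budget); the size-deviation
    cost is subtracted. psi and cost must be precomputed.
    """
    psi = cluster.psi
    gain = 0.0
    for member in cluster.members:
        gain += min(psi, ledger.budgets[member])
    return gain - cluster.cost


def map_profit(
    pool: list[FunctionalCluster],
    ledger: BudgetLedger,
    params: ScoringParams,
) -> tuple[FunctionalCluster, BudgetLedger, float]:
    """One greedy iteration: pick the max-profit candidate and commit it.

    Evaluates every candidate's net profit against *ledger*, picks the
    argmax (ties go to the candidate earliest in the pool, i.e. earliest in
    term order), then decays the winner's members' budgets by
    ``max(0, (d/10) * (b(i) - psi))``. Returns the winner, the committed
    ledger and the winning net profit. The input ledger is not mutated.
    """
    if not pool:
        raise ValueError("candidate pool is empty")

    best = None
    best_profit = None
    for cluster in pool:
        profit = cluster_profit(cluster, ledger)
        if best_profit is None or profit > best_profit:
            best, best_profit = cluster, profit

    committed = ledger.copy()
    decay = params.d / 10.0
    psi = best.psi
    for member in best.members:
        remaining = committed.budgets[member]
        committed.budgets[member] = max(0.0, decay * (remaining - psi))
    committed.total_profit += best_profit
    return best, committed, best_profit


def summarize(
    network: nx.Graph,
    pool: list[FunctionalCluster],
    params: ScoringParams,
) -> tuple[list[FunctionalCluster], list[SelectionRecord], BudgetLedger]:
    """Greedily select min(k, |pool|) clusters from the candidate pool.

    Scores the pool (psi, cost), then repeatedly calls :func:`map_profit`,
    removing each winner from the pool. Returns the selected clusters in
    selection order, the selection trace and the final budget ledger. If k
    exceeds the pool size the whole pool is returned with a warning.
    """
    if not pool:
        raise ValueError("candidate pool is empty")
    if params.k > len(pool):
        logger.warning(
            "k=%d exceeds pool size %d; returning the entire pool",
            params.k,
            len(pool),
        )

    score_pool(pool, network.number_of_nodes(), params.k)
    remaining = list(pool)
    ledger = BudgetLedger.fresh(network.nodes, params.b)
    selected: list[FunctionalCluster] = []
    trace: list[SelectionRecord] = []

    for iteration in range(min(params.k, len(pool))):
        best, ledger, profit = map_profit(remaining, ledger, params)
        remaining.remove(best)
        selected.append(best)
        trace.append(
            SelectionRecord(
                iteration=iteration + 1,
                term=best.term,
                profit=profit,
                size=best.size,
            )
        )
    return selected, trace, ledger
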