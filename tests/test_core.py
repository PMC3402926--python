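import itertools
import logging
import random

import pytest

from funcsum.core import (
    cluster_profit,
    map_profit,
    score_pool,
    size_deviation_cost,
    structural_information,
    summarize,
)
from funcsum.types import BudgetLedger, ScoringParams

from conftest import make_cluster, make_network


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "members,edges,expected",
    [
        ({"a", "b", "c"}, [("a", "b", 1.0), ("b", "c", 1.0)], 2 / 3),
        ({"a", "b", "c"}, [], 0.0),
        ({"a", "b", "c", "d"}, [("a", "b", 2.0), ("b", "c", 0.5), ("c", "d", 1.5)], 1.0),
    ],
)
def test_structural_information(members, edges, expected):
    cluster = make_cluster("t", members, edges)
    assert structural_information(cluster) == pytest.approx(expected)


@pytest.mark.parametrize(
    "size,n,k,expected",
    [
        (20, 100, 5, 0.0),     # size equals |V|/k exactly
        (30, 100, 5, 100.0),   # 10 above expectation
        (10, 100, 5, 100.0),   # symmetric 10 below
    ],
)
def test_size_deviation_cost(size, n, k, expected):
    assert size_deviation_cost(size, n, k) == expected


# ---------------------------------------------------------------------------
# map_profit
# ---------------------------------------------------------------------------

def ledger_for(proteins, b):
    return BudgetLedger.fresh(proteins, b)


def test_single_candidate_profit_and_d0_commit():
    cluster = make_cluster("t", {"a", "b"}, psi=1.0, cost=0.0)
    params = ScoringParams(k=1, b=3.0, d=0.0)
    best, committed, profit = map_profit([cluster], ledger_for("ab", 3.0), params)
    assert best is cluster
    assert profit == pytest.approx(2.0)
    assert committed.budgets == {"a": 0.0, "b": 0.0}


def test_budget_limited_member_contributes_remaining_budget():
    cluster = make_cluster("t", {"a"}, psi=1.0, cost=0.0)
    ledger = ledger_for("a", 3.0)
    ledger.budgets["a"] = 0.5
    assert cluster_profit(cluster, ledger) == pytest.approx(0.5)


def test_decay_commit_formula():
    # d=5, b(i)=3, psi=1 -> new budget 0.5 * (3 - 1) = 1.0
    cluster = make_cluster("t", {"a"}, psi=1.0, cost=0.0)
    params = ScoringParams(k=1, b=3.0, d=5.0)
    _, committed, _ = map_profit([cluster], ledger_for("a", 3.0), params)
    assert committed.budgets["a"] == pytest.approx(1.0)


def test_decay_clamped_at_zero_when_budget_below_psi():
    cluster = make_cluster("t", {"a"}, psi=2.0, cost=0.0)
    params = ScoringParams(k=1, b=3.0, d=10.0)
    ledger = ledger_for("a", 3.0)
    ledger.budgets["a"] = 1.0
    _, committed, _ = map_profit([cluster], ledger, params)
    assert committed.budgets["a"] == 0.0


def test_map_profit_matches_exhaustive_argmax_on_toy():
    net = make_network(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0),
         ("d", "e", 1.0), ("e", "f", 1.0), ("a", "c", 1.0)]
    )
    pool = [
        make_cluster("t1", {"a", "b", "c"}, [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]),
        make_cluster("t2", {"c", "d", "e"}, [("c", "d", 1), ("d", "e", 1)]),
        make_cluster("t3", {"e", "f"}, [("e", "f", 1)]),
    ]
    params = ScoringParams(k=2, b=3.0)
    score_pool(pool, net.number_of_nodes(), params.k)
    ledger = ledger_for(net.nodes, params.b)
    profits = [cluster_profit(c, ledger) for c in pool]
    best, _, profit = map_profit(pool, ledger, params)
    assert profit == max(profits)
    assert best is pool[profits.index(max(profits))]


def test_tie_breaks_to_earliest_in_term_order():
    # identical extents -> identical profits; first in pool order must win
    pool = [
        make_cluster("early", {"a", "b"}, [("a", "b", 1)], psi=0.5, cost=0.0),
        make_cluster("late", {"a", "b"}, [("a", "b", 1)], psi=0.5, cost=0.0),
    ]
    best, _, _ = map_profit(pool, ledger_for("ab", 3.0), ScoringParams(k=2))
    assert best.term == "early"


def test_map_profit_empty_pool_errors():
    with pytest.raises(ValueError, match="empty"):
        map_profit([], ledger_for("a", 3.0), ScoringParams(k=1))


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------

def small_instance():
    net = make_network(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "a", 1.0), ("c", "d", 1.0)]
    )
    pool = [
        make_cluster("t1", {"a", "b", "c"},
                     [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]),
        make_cluster("t2", {"c", "d"}, [("c", "d", 1)]),
        make_cluster("t3", {"a", "d"}, []),
    ]
    return net, pool


def test_k1_selects_single_cluster_argmax():
    net, pool = small_instance()
    params = ScoringParams(k=1, b=3.0)
    selected, trace, _ = summarize(net, pool, params)
    assert len(selected) == 1
    # independent check: profit of every candidate from a fresh ledger
    fresh = ledger_for(net.nodes, params.b)
    profits = [cluster_profit(c, fresh) for c in pool]
    assert selected[0] is pool[profits.index(max(profits))]
    assert trace[0].profit == pytest.approx(max(profits))


def test_k_exceeding_pool_returns_all_with_warning(caplog):
    net, pool = small_instance()
    with caplog.at_level(logging.WARNING):
        selected, trace, _ = summarize(net, pool, ScoringParams(k=10))
    assert len(selected) == len(pool)
    assert any("exceeds pool size" in r.message for r in caplog.records)


def test_determinism():
    net, pool = small_instance()

    def run():
        fresh = [make_cluster(c.term, c.members, [
            (a, b, w) for a, b, w in c.induced_edges]) for c in pool]
        _, trace, _ = summarize(net, fresh, ScoringParams(k=3, b=3.0, d=5.0))
        return [(r.term, r.profit, r.size) for r in trace]

    assert run() == run()


def test_selected_clusters_are_distinct_and_removed_from_pool():
    net, pool = small_instance()
    selected, _, _ = summarize(net, pool, ScoringParams(k=3))
    assert len({c.term for c in selected}) == 3


# ---------------------------------------------------------------------------
# independent sequential-profit simulator (oracle)
# ---------------------------------------------------------------------------

def independent_psi(members, network):
    total = sum(
        d["weight"]
        for a, b, d in network.edges(data=True)
        if a in members and b in members
    )
    return total / len(members)


def simulate_sequence(order, network, b, d, k):
    """Replay the budget recurrence for a fixed cluster sequence."""
    budgets = {v: b for v in network.nodes}
    total = 0.0
    n = network.number_of_nodes()
    for members in order:
        psi = independent_psi(members, network)
        cost = (len(members) - n / k) ** 2
        gain = sum(min(psi, budgets[i]) for i in members) - cost
        total += gain
        for i in members:
            budgets[i] = max(0.0, (d / 10.0) * (budgets[i] - psi))
    return total, budgets


def random_instance(rng):
    n = rng.randint(4, 12)
    vertices = [f"v{i}" for i in range(n)]
    edges = [
        (a, b, round(rng.uniform(0.1, 3.0), 2))
        for a, b in itertools.combinations(vertices, 2)
        if rng.random() < 0.3
    ]
    net = make_network(edges, nodes=vertices)
    n_clusters = rng.randint(2, 8)
    pool = []
    for idx in range(n_clusters):
        members = rng.sample(vertices, rng.randint(2, n))
        sub = net.subgraph(members)
        pool.append(
            make_cluster(
                f"T{idx}",
                members,
                [(a, b, d["weight"]) for a, b, d in sub.edges(data=True)],
            )
        )
    params = ScoringParams(
        k=rng.randint(1, min(4, n_clusters)),
        b=rng.choice([0.5, 1.0, 3.0, 9.0]),
        d=rng.choice([0.0, 2.0, 5.0, 10.0]),
    )
    return net, pool, params


def test_greedy_matches_stepwise_exhaustive_oracle():
    """Each greedy iteration must agree with a from-scratch re-evaluation of
    every candidate's profit at the current ledger state, and the final
    ledger must match the independent budget-recurrence simulator."""
    rng = random.Random(20120321)
    for _ in range(100):
        net, pool, params = random_instance(rng)
        selected, trace, ledger = summarize(net, [
            make_cluster(c.term, c.members, c.induced_edges) for c in pool
        ], params)

        budgets = {v: params.b for v in net.nodes}
        n = net.number_of_nodes()
        remaining = list(pool)
        for record in trace:
            # independent profit of every remaining candidate
            profits = []
            for c in remaining:
                psi = independent_psi(c.members, net)
                cost = (len(c.members) - n / params.k) ** 2
                profits.append(
                    sum(min(psi, budgets[i]) for i in c.members) - cost
                )
            best_idx = profits.index(max(profits))
            assert remaining[best_idx].term == record.term
            assert record.profit == pytest.approx(profits[best_idx])
            chosen = remaining.pop(best_idx)
            psi = independent_psi(chosen.members, net)
            for i in chosen.members:
                budgets[i] = max(0.0, (params.d / 10.0) * (budgets[i] - psi))

        for v in net.nodes:
            assert ledger.budgets[v] == pytest.approx(budgets[v])


def test_budgets_never_negative_and_bounded():
    rng = random.Random(99)
    for _ in range(20):
        net, pool, params = random_instance(rng)
        _, _, ledger = summarize(net, pool, params)
        for budget in ledger.budgets.values():
            assert 0.0 <= budget <= params.b


# ---------------------------------------------------------------------------
# greedy vs. all ordered k-subsets on an overlapping-cluster toy
# ---------------------------------------------------------------------------

def overlapping_toy():
    """9 proteins, one dense community and one sparse one, with clusters
    overlapping at the boundary (the kind of instance the profit model is
    built to arbitrate)."""
    net = make_network(
        [
            ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),  # dense core
            ("b", "d", 1.0), ("c", "e", 1.0),                   # sparse arm
            ("d", "f", 1.0),
            ("f", "g", 1.0), ("g", "h", 1.0), ("h", "i", 1.0),  # chain
        ]
    )
    member_sets = {
        "dense": {"a", "b", "c"},
        "sparse": {"b", "c", "d", "e"},
        "pairlet": {"b", "c"},
        "bridge": {"d", "e", "f"},
        "chain": {"f", "g", "h", "i"},
    }
    pool = []
    for term, members in member_sets.items():
        sub = net.subgraph(members)
        pool.append(
            make_cluster(
                term, members, [(x, y, d["weight"]) for x, y, d in sub.edges(data=True)]
            )
        )
    return net, pool


def test_greedy_profit_beats_every_ordered_3_subset():
    net, pool = overlapping_toy()
    params = ScoringParams(k=3, b=3.0, d=0.0)
    _, trace, _ = summarize(
        net,
        [make_cluster(c.term, c.members, c.induced_edges) for c in pool],
        params,
    )
    greedy_total = sum(r.profit for r in trace)

    best = float("-inf")
    for order in itertools.permutations([c.members for c in pool], 3):
        total, _ = simulate_sequence(order, net, params.b, params.d, params.k)
        best = max(best, total)
    assert greedy_total == pytest.approx(best) or greedy_total > best
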