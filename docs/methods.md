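# Methods

## Problem and model

`funcsum` summarizes a weighted, undirected protein interaction network
`G = (V, E, ω)` into k interconnected, possibly overlapping functional
clusters. The unit of summarization is the *term-induced cluster*: for a GO
term `u`, `C(u)` is the subgraph induced by every protein whose propagated
term association vector contains `u`. Association vectors obey the true-path
rule — a protein annotated with a term implicitly carries every ancestor of
that term reachable via the retained DAG relations (`is_a` and `part_of` by
default; configurable, since GO practice varies on whether regulates-type
edges should propagate).

Cluster value is the ratio-association density
`ψ(u) = Σ_{i,j∈C(u)} ω_ij / |C(u)|`, with each undirected edge counted
once. The alternative convention (ordered pairs, a factor of 2) would not
change candidate rankings but would change profit magnitudes relative to
the budget `b`; the single-count convention matches the induced-subgraph
reading of the sum and is fixed throughout. A correction term subtracting
the expected density of a random cluster is deliberately omitted: with
nonnegative weights, density alone already orders clusters by
self-information, so `ψ ≥ 0` always holds here and the negative-ψ regime
never arises.

## Greedy selection under budgets

Each protein starts with budget `b` (default 3). A candidate's net profit at
the current ledger is `Σ_{i∈C(u)} min(ψ(u), b(i)) − c(u)` with size cost
`c(u) = (|C(u)| − |V|/k)²`; the expected cluster cardinality `|V|/k` ties
the cost to the requested granularity and discourages the greedy from
grabbing huge general terms (e.g. DAG roots) early. After a cluster is
committed its members' budgets decay to `max(0, (d/10)(b(i) − ψ))`. The
clamp at zero unifies the two equivalent formulations of the decay (the
recurrence saturates extraction at `b(i)` exactly when `b(i) < ψ`). Within
the commit, `ψ` is that of the just-selected cluster.

Selection is a plain argmax per iteration. Ties are broken toward the
earliest term in the topological term order — the deterministic total order
over terms (parents before children, lexicographic among incomparable
terms). A consequence worth noting: two terms with identical extents both
stay in the candidate pool, but once one is selected, budget depletion
makes its twin unprofitable, so no ad-hoc deduplication is needed. If every
remaining candidate has non-positive net profit the argmax is still taken
(the summary must reach k clusters); if `k` exceeds the pool size the whole
pool is returned with a warning rather than an error, since the user's
intent — maximum detail — is unambiguous. Selected clusters are removed
from the pool and never re-selected.

The candidate pool is filtered only by `min_size` (default 2 — a singleton
has no structure to score) and `max_size_fraction` (default 1.0, i.e. no
upper cut: the size cost already penalizes root-scale clusters). Both are
exposed rather than hidden because there is no principled universal value.

## Association significance

Under the null, two uniformly random proteins interact with probability
`p_i = 2|E|/(|V|(|V|−1))` (weights ignored; the null counts interactions).
For clusters `C(u)`, `C(v)`, the `n = |C(u)|·|C(v)|` member pairs are
treated as iid Bernoulli trials and the observed inter-cluster edge count
`oc` is scored by the inclusive upper tail `P(X ≥ oc)`, computed via the
binomial survival function (agreeing with direct summation to ≤ 1e-12 for
n ≤ 50; verified in tests). `oc = 0` gives p = 1 by convention (full mass).
For overlapping clusters `n` is the plain product — no correction for
shared members — and an edge wholly inside the intersection counts once
toward `oc`; fidelity to the simple product model is preferred over
statistical refinement, and the model is symmetric in (u, v) either way.

A pair becomes an FSG edge when `p ≤ 2β/|S|²` (default) — the Bonferroni
correction over the ~|S|²/2 pairwise tests. The exact form
`2β/(|S|(|S|−1))` is available via `threshold_form="kk1"`; the squared form
is the default because it is the one that defines the summary-graph
acceptance rule, and the applied threshold is logged for audit. All pairwise
tests, significant or not, are retained on the summary object and written to
`pairwise_tests.tsv`.

## Metrics

- **coverage** — proteins covered by the summary over proteins covered by
  the whole candidate pool (i.e. annotated, clusterable proteins).
- **redundancy** — Σ cluster sizes over the size of their union; equals 1
  exactly for pairwise-disjoint clusters, which is its floor.
- **SIC** — `Σ −ψ(u)·|V(u)|·ln p(V(u))` with `p(V(u)) = |V(u)| / #annotated`.
  Two underdetermined choices are fixed here: natural log (base only
  rescales, never reorders summaries) and annotated proteins as the
  denominator (consistent with the rule that unannotated proteins are not
  considered by any metric). Note the formula's two opposing size factors:
  `|V(u)|` up-weights large clusters while `−ln p` up-weights rare (small)
  ones; the formula is implemented verbatim and the tension left as-is.
- **precision / recall / F** — each cluster is matched to the reference
  group with maximum overlap (ties lexicographic); purity is the matched
  fraction of the cluster; group recall is the group's coverage by the
  union of clusters matched to it, with unmatched groups contributing 0
  (without this, a clusterer could ignore groups and still score recall 1);
  precision/recall are the means and F their harmonic mean.
- **representative function** — per cluster, the term with the best
  one-sided hypergeometric over-representation p-value over the universe of
  annotated proteins (no multiple-testing correction — assignment is by
  best p-value, not by a significance claim); ties resolve to the earlier
  term in the term order. Clusters produced by the summarizer are perfectly
  representative by construction (membership *is* the annotation
  predicate), which the tests assert as an identity.
- **degree distribution / hubs** — cluster degrees in the FSG, their
  empirical CDF, and the top-m most connected clusters (default m = 15).

## Synthetic data

The random generator draws each unordered vertex pair as an edge with
probability 0.0025 and each (vertex, term) annotation with probability 0.02
(both configurable), over a flat one-root DAG so that propagation adds only
the root and the per-term annotation rate is exactly the Bernoulli rate.
Expected edge counts under the unordered-pair convention are
`|V|(|V|−1)/2 · p`; a generator flag switches to the ordered-pair
convention (effective unordered probability `1 − (1−p)²`, roughly doubling
density) because published edge-count figures for such generators are
ambiguous between the two readings; the generator reports its expectation
alongside the draw.

The planted-module generator emulates a reference network of disjoint
attribute-coherent groups: 5 groups of 20 proteins (defaults), each group
fully annotated with one defining term, intra-group edge probability 0.3,
inter-group 0.005, plus 10 background terms annotating any vertex with
probability 0.05 to give the pool incoherent competitors. Defaults were
chosen so that a group's expected ψ (≈ 2.9) sits near the default budget
and the expected inter-group edge counts sit well below the Bonferroni
threshold, which keeps the no-edge FSG check stable. What these fixtures do
*not* emulate: scale-free degree structure, DAG depth, annotation bias
toward hubs, or evidence-code heterogeneity — so passing recovery tests
show correctness of the machinery, not performance on real interactomes.

Experiment scales used by the test suite (chosen as desk-scale analogs):
trend and recovery experiments run 10 seeds on the 100-protein planted
network; the b/d redundancy-trend experiment summarizes at k = 8, above the
planted group count, because at k = 5 the recovered summary is disjoint for
any (b, d) and the trend is vacuous; recovery compares k = 5 against k = 2
and k = 8. Greedy-vs-exhaustive equivalence uses 100 random instances of at
most 12 vertices and 8 candidates, where ordered-subset enumeration is
exact and fast.

## Numerical and degenerate-input choices

- Binomial and hypergeometric tails go through scipy survival functions;
  tests pin them to literal summation oracles at 1e-12 absolute.
- Weights must be nonnegative; negative weights are rejected at parse time.
- Duplicate edges in input keep the last weight read (logged, so users can
  audit); self-loops are dropped with a logged count.
- An empty candidate pool raises with advice to relax filters; a singleton
  summary has no pairs to test and yields an edgeless FSG.
- All randomness in the synthetic module flows through one seeded
  `numpy` generator per call; fixed seed ⇒ byte-identical fixtures.

## Known limitations

- Greedy selection carries no approximation guarantee for the underlying
  NP-hard profit maximization; the tests verify greedy-vs-oracle step
  equivalence and (on a small overlapping-cluster instance) global
  optimality by enumeration, not a worst-case bound.
- The binomial edge model ignores weights and degree heterogeneity; real
  interactomes violate the iid-pair assumption.
- The redundancy trend in b and d is monotone in expectation at the tested
  scales but is not a theorem; at granularities far above the natural
  module count the trend can be non-monotone seed-to-seed.
- Identifier mapping between annotation and interaction databases is out of
  scope; identifiers must already agree.
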