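# Methods

## Model and procedure

**Per-perturbation level.** The input is a bipartite protein–DNA graph:
TFs on one side, genes on the other, edge weights `Edge_Weight(x, g) > 0`
expressing binding reliability. A TF's cost is
`w(x) = 1 / Σ_g Edge_Weight(x, g)`, summed over the TF's *full*
neighborhood in the input graph (not the perturbation-induced subgraph):
the cost expresses how reliable and prolific a regulator is overall, which
is a property of the TF, not of one experiment. A flag
(`induced_weights=True`) switches to induced-only sums for sensitivity
analysis.

Given one perturbation's DE gene set, each retained gene `g` contributes
the subset `S_g` = TFs binding it, and the cooperative TF set is the
minimum-weight `H` with `|S_g ∩ H| ≥ t` for all `g` — the weighted
t-cover hitting set. With `t = 1` this degenerates to plain set cover and
returns single "explaining" TFs; `t ≥ 2` forces co-covering TFs, which is
the cooperative-module premise. Each connected component of the induced
bipartite subgraph is solved independently and the per-component witnesses
are unioned.

Genes of degree < t cannot be covered `t` times. Two policies, chosen
explicitly by the caller: **drop** removes the gene from the instance and
reports it (the default; also shrinks `n` and speeds up the solver);
**pad** adds per-gene dummy elements so the subset reaches size `t`,
which effectively lowers that gene's coverage requirement to its degree.
Dummies carry weight 0 (padding must not distort the objective; covers
differing only in dummies tie and are resolved lexicographically) and are
stripped from all reported witnesses.

**Exact solver.** Dynamic programming over hit vectors
`hit(H) = [c_1..c_n]`, `c_i = min(t, |S_i ∩ H|)`. Elements are added one
at a time; per distinct hit vector only the lightest sub-solution — or the
`top_k` lightest with pairwise-distinct witnesses — survives. Correctness
rests on interchangeability: if `hit(H1) = hit(H2)`, any extension
disjoint from both preserves the equality, so discarding the heavier
witness can never lose the optimum (this is exercised as a property test).
Subsets are sorted by non-decreasing size and elements so that each subset
prefix's union occupies an order prefix; once the last element of a subset
has been processed, states with that subset below `t` are pruned. The
state store is a hash map keyed by the count tuple (any associative map
with O(log) or amortized O(1) access would do). Worst-case `(t+1)^n`
states; with many subsets of size ≤ d the effective base drops to
`base(t, d) = (t+1)^(d/(d+log2(t+1)))`, e.g. 2.303/2.692/3.001 for
t=2/3/4 at d=5 — a ≥ 2787-fold (t=2) to ≥ 4.46·10⁶-fold (t=4) reduction
at n = 30. Instrumentation (`SolverStats`) records the store size per step
so both bounds are assertable in tests.

**Numerical choices.** Weights accumulate in double precision; weight
comparisons use an absolute tolerance of 1e-9, with ties between
equal-weight witnesses broken by the lexicographic sorted-id tuple, making
every output deterministic. Subset-size ties in the processing order are
broken by the sorted member tuple; elements within a subset block
lexicographically. An empty family (all genes dropped) is vacuously
covered: the empty witness of weight 0 is returned with a warning. The
brute-force oracle refuses universes above 20 elements.

**Systems level.** Two TFs "cooperate in an instance" when both are in
that instance's solution *and* share ≥ 1 common DE target there; the
TF–TF relation-graph edge accumulates those common-target counts over all
instances (pairs with zero shared targets add no edge — a zero-weight
edge would manufacture cliques out of coincidental co-membership).
Relation graphs for different `t` are kept strictly separate. Soft
cliques = 3-/4-cliques of this graph, weight = sum of the 3 or 6 edge
weights, ranked descending with lexicographic tie-break. Hard cliques are
found per instance by enumerating, for each DE gene, all size-3/4 subsets
of its TF neighborhood and counting genes per TF set (weight = joint
target count); totals are summed across instances. By default all TFs
adjacent to an instance's genes are hard-clique candidates, with an
option to restrict to the instance's solution TFs. Clique sizes beyond 4
are out of scope (genes binding > 5 TFs are rare in the data regime this
targets). Interaction enrichment reports, for k = 0..C(size,2), the
fraction of cliques with ≥ k interacting member pairs, against `n_random`
TF groups sampled uniformly without replacement from the full TF set of
the protein–DNA graph.

## Synthetic worlds

The generator emulates the *structure* the solver exploits, not any real
organism's network. Gene degrees are drawn from a banded mixture matching
the cumulative profile P(deg ≤ 3) = 0.70, P(deg ≤ 5) = 0.85,
P(deg ≤ 10) = 0.96 (uniform within bands 1–3, 4–5, 6–10, 11–15); TFs are
attached per gene without replacement, uniformly except for planted-module
TFs (below); edge weights are uniform on [0.5, 1.0]. A single seed is
split (`numpy.random.SeedSequence.spawn`) into independent streams for
graph, planting, instances and interactions.

Default study conditions: 100 TFs, 2000 genes, 10 perturbation instances
of 32 DE genes each, one planted 3-TF module wired to 30 common target
genes; each module-bearing instance contains 10 planted targets plus 22
background genes. Planted edges are 2× more reliable than background
(`planted_boost = 2.0`) and module TFs receive 2× the background
attachment propensity (`planted_attachment = 2.0`): cooperative master
regulators are hubs with reliable binding, and both properties matter for
recovery. With every planted gene wired to all three module TFs, two
cheap module TFs already double-cover the planted targets at t = 2; it is
the module TFs' hub-level background coverage (obligate degree-2 genes)
that forces the third member into solutions, closing the module triangle
in the relation graph. At attachment 2.0 the t = 2 pipeline ranks the
planted module as the top soft 3-clique essentially always, while t = 1 —
which never needs co-coverage — ranks it markedly lower on average,
reproducing the qualitative t = 2 vs t = 1 contrast the method is built
on. The interaction generator marks all within-module pairs as
interacting plus independent background pairs (default rate 0.02).

What the synthetic worlds do *not* emulate: real ChIP-chip weight
distributions, correlated perturbation responses, condition-dependent
binding, or noise in DE calling. Passing tests therefore demonstrate that
the algorithms recover structure that is present in the stated form, not
that any particular biological network satisfies the model's premises.

## Problem sizes in the shipped suites

The oracle-equivalence suite uses 220 random instances with m ≤ 14
elements, n ≤ 8 subsets, t ≤ 3 — small enough for the 2^m exhaustive
oracle while exercising every pruning path; the recovery suite runs 20
seeded replicates of the default world at both t = 2 and t = 1. The
acceptance script's quantities are closed-form and evaluated directly.

## Known limitations

- The solver is exponential in the number of retained genes per component;
  it is practical in the low-degree regime it targets, and the drop policy
  reduces `n` further, but dense components with many high-degree genes
  can exhaust memory. No approximation fallback is provided by design.
- TF weights depend on the input graph's weighting; unweighted graphs can
  be used (all edge weights 1) but then the cover favors high-degree TFs
  only.
- Hard-clique enumeration is per-gene combinatorial (C(degree, size)); it
  assumes the same bounded-degree regime.
- The interaction evaluation reports raw cumulative curves; no
  significance testing is attempted.
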