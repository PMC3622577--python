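"""Exact solver for the weighted t-cover hitting set problem.

The problem: given a universe ``X`` of *m* elements with positive weights
``w``, a family ``T = {S_1, ..., S_n}`` of subsets of ``X`` and an integer
``t >= 1``, find a subset ``H`` of ``X`` of minimum total weight such that
every subset in the family contains at least ``t`` elements of ``H``
(a *set multicover* by elements, here called a *t-cover hitting set*).

The problem is NP-hard.  The solver here is an exact dynamic program over
*hit vectors*: the state of a partial solution ``H`` is
``hit(H) = [c_1, ..., c_n]`` with ``c_i = min(t, |S_i ∩ H|)``.  Two partial
solutions with equal hit vectors are interchangeable with respect to any
future extension, so per state only the lightest witness (or the ``k``
lightest, for top-k enumeration) is retained.  At most ``(t+1)^n`` states
can ever coexist; processing elements in a subset-aware order and pruning
states that can no longer satisfy an already-exhausted subset lowers the
effective exponential base to ``(t+1)^(d/(d+log2(t+1)))`` when enough
subsets have size at most ``d`` — the regime found in protein-DNA binding
graphs, where most genes bind only a handful of transcription factors.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

__all__ = [
    "HittingSetInstance",
    "CoverSolution",
    "SolverStats",
    "InfeasibleInstanceError",
    "sort_instance",
    "hit_vector",
    "solve_weighted_t_cover",
    "brute_force_t_cover",
    "effective_base",
    "speedup_bound",
]

#: absolute tolerance used when comparing accumulated floating-point weights
WEIGHT_TOL = 1e-9

#: brute-force oracle refuses universes larger than this (2^m enumeration)
BRUTE_FORCE_MAX_ELEMENTS = 20


class InfeasibleInstanceError(ValueError):
    """Raised when some subset can never reach the coverage requirement."""

    def __init__(self, subset: frozenset, t: int):
        self.subset = subset
        self.t = t
        members = ",".join(sorted(map(str, subset)))
        super().__init__(
            f"subset {{{members}}} has size {len(subset)} < t={t}; "
            "it can never be covered t times"
        )


@dataclass(frozen=True)
class HittingSetInstance:
    """A weighted t-cover hitting set instance ``(X, T, w, t)``.

    Parameters
    ----------
    elements
        Ordered element ids (the universe ``X``).
    weights
        Map element id -> positive weight.  Elements listed in ``dummies``
        may carry weight zero; they model padding of undersized subsets and
        are excluded from reported witnesses.
    family
        Ordered subsets of element ids (``T``).
    t
        Coverage requirement (each subset must contain >= t chosen elements).
    dummies
        Zero-weight padding element ids (optional).
    """

    elements: tuple
    weights: Mapping
    family: tuple
    t: int
    dummies: frozenset = frozenset()

    def __post_init__(self):
        elements = tuple(self.elements)
        family = tuple(frozenset(s) for s in self.family)
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "dummies", frozenset(self.dummies))
        if len(set(elements)) != len(elements):
            raise ValueError("element ids must be unique")
        if self.t < 1:
            raise ValueError(f"t must be a positive integer, got {self.t}")
        known = set(elements)
        if set(self.weights) != known:
            raise ValueError("weights must be given for exactly the elements")
        for u, w in self.weights.items():
            if u in self.dummies:
                if w < 0:
                    raise ValueError(f"dummy element {u!r} has negative weight {w}")
            elif w <= 0:
                raise ValueError(f"element {u!r} has non-positive weight {w}")
        for s in family:
            if not s:
                raise ValueError("subsets must be non-empty")
            if not s <= known:
                raise ValueError(f"subset {sorted(s)} references unknown elements")

    @property
    def m(self) -> int:
        return len(self.elements)

    @property
    def n(self) -> int:
        return len(self.family)

    def witness_weight(self, witness: Iterable) -> float:
        return float(sum(self.weights[u] for u in witness))


@dataclass(frozen=True)
class CoverSolution:
    """A feasible cover: witness set, its weight, per-subset coverage counts."""

    witness: frozenset
    weight: float
    coverage: tuple

    def strip_dummies(self, dummies: frozenset) -> "CoverSolution":
        return CoverSolution(self.witness - dummies, self.weight, self.coverage)


@dataclass
class SolverStats:
    """Instrumentation of one dynamic-programming run."""

    max_states: int = 0
    states_per_step: list = field(default_factory=list)

    def record(self, n_states: int) -> None:
        self.states_per_step.append(n_states)
        if n_states > self.max_states:
            self.max_states = n_states


# ---------------------------------------------------------------------------
# ordering


def _subset_key(s: frozenset):
    return (len(s), tuple(sorted(s)))


def sort_instance(instance: HittingSetInstance):
    """Return ``(element_order, subset_order)`` for the dynamic program.

    Subsets are ordered by non-decreasing size (ties by the sorted member
    tuple).  Elements are ordered so that for every prefix of subsets
    ``S_1..S_j`` the elements of their union come first: the order is
    ``S_1, S_2 - X_1, ..., S_n - X_{n-1}`` with ``X_j`` the running union,
    each block sorted lexicographically; elements in no subset come last.
    """
    family = sorted(instance.family, key=_subset_key)
    order: list = []
    seen: set = set()
    for s in family:
        fresh = sorted(s - seen)
        order.extend(fresh)
        seen.update(fresh)
    order.extend(sorted(set(instance.elements) - seen))
    return tuple(order), tuple(family)


def hit_vector(witness: Iterable, instance: HittingSetInstance):
    """``hit(H)``: per-subset count of witness members, capped at ``t``."""
    witness = set(witness)
    unknown = witness - set(instance.elements)
    if unknown:
        raise ValueError(f"unknown element ids in witness: {sorted(unknown)}")
    t = instance.t
    return tuple(min(t, len(s & witness)) for s in instance.family)


# ---------------------------------------------------------------------------
# dynamic program


def _cmp_subsolutions(a, b):
    """Order (weight, witness) pairs: lighter first, ties by witness id tuple."""
    if a[0] < b[0] - WEIGHT_TOL:
        return -1
    if b[0] < a[0] - WEIGHT_TOL:
        return 1
    return -1 if a[1] < b[1] else (1 if a[1] > b[1] else 0)


_SUBSOL_KEY = functools.cmp_to_key(_cmp_subsolutions)


def _merge(store: dict, state: tuple, candidates, top_k: int) -> None:
    """Fold candidate sub-solutions into the per-state top-k list."""
    existing = store.get(state)
    if existing is None:
        pool = list(candidates)
    else:
        pool = existing + list(candidates)
    seen: set = set()
    unique = []
    for sub in sorted(pool, key=_SUBSOL_KEY):
        if sub[1] not in seen:
            seen.add(sub[1])
            unique.append(sub)
            if len(unique) == top_k:
                break
    store[state] = unique


def solve_weighted_t_cover(
    instance: HittingSetInstance,
    top_k: int = 1,
    *,
    stats: SolverStats | None = None,
):
    """Solve an instance exactly; return up to ``top_k`` lightest covers.

    The first returned solution has provably minimum weight; solutions are
    sorted by non-decreasing weight and have pairwise distinct witnesses.
    An empty family is vacuously covered: the empty solution is returned
    with a warning.

    Raises
    ------
    InfeasibleInstanceError
        If some subset has fewer than ``t`` elements.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not instance.family:
        warnings.warn(
            "empty family: coverage is vacuously satisfied, returning the "
            "empty solution",
            stacklevel=2,
        )
        if stats is not None:
            stats.record(1)
        return [CoverSolution(frozenset(), 0.0, ())]
    for s in instance.family:
        if len(s) < instance.t:
            raise InfeasibleInstanceError(s, instance.t)

    t = instance.t
    order, family = sort_instance(instance)
    n = len(family)
    membership = {u: tuple(j for j, s in enumerate(family) if u in s) for u in order}
    pos = {u: i for i, u in enumerate(order)}
    # deadline[j]: index of the last element of S_j in the processing order;
    # past it no future element can raise c_j, so states with c_j < t die.
    finish_at: dict = {}
    for j, s in enumerate(family):
        finish_at.setdefault(max(pos[u] for u in s), []).append(j)

    zero = (0,) * n
    store: dict = {zero: [(0.0, ())]}
    if stats is not None:
        stats.record(1)
    for i, u in enumerate(order):
        if not membership[u] and i not in finish_at:
            continue  # element in no subset: never part of an optimal cover
        wu = instance.weights[u]
        new_store: dict = {}
        for state, subs in store.items():
            _merge(new_store, state, subs, top_k)
            bumped = list(state)
            for j in membership[u]:
                if bumped[j] < t:
                    bumped[j] += 1
            bumped_state = tuple(bumped)
            taken = [
                (w + wu, tuple(sorted(wit + (u,)))) for w, wit in subs
            ]
            _merge(new_store, bumped_state, taken, top_k)
        for j in finish_at.get(i, ()):
            new_store = {st: v for st, v in new_store.items() if st[j] >= t}
        store = new_store
        if stats is not None:
            stats.record(len(store))
        if not store:
            break

    full = (t,) * n
    finals = store.get(full, [])
    if not finals:
        # cannot happen when every subset has size >= t
        raise InfeasibleInstanceError(min(family, key=_subset_key), t)
    out = []
    for w, wit in finals[:top_k]:
        witness = frozenset(wit)
        out.append(
            CoverSolution(witness, instance.witness_weight(witness),
                          hit_vector(witness, instance))
        )
    return out


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_t_cover(instance: HittingSetInstance) -> CoverSolution:
    """Exhaustive minimum-weight t-cover over all ``2^m`` element subsets.

    Independent of the dynamic program; intended as a verification oracle
    on small instances only.  Ties between equal-weight optima are broken
    by the lexicographically smallest witness id tuple.
    """
    m = instance.m
    if m > BRUTE_FORCE_MAX_ELEMENTS:
        raise ValueError(
            f"instance has {m} elements; brute force is limited to "
            f"{BRUTE_FORCE_MAX_ELEMENTS}"
        )
    if not instance.family:
        warnings.warn("empty family: returning the empty solution", stacklevel=2)
        return CoverSolution(frozenset(), 0.0, ())
    for s in instance.family:
        if len(s) < instance.t:
            raise InfeasibleInstanceError(s, instance.t)
    t = instance.t
    elements = sorted(instance.elements)
    best = None
    best_key = None
    for r in range(m + 1):
        for combo in itertools.combinations(elements, r):
            chosen = set(combo)
            if all(len(s & chosen) >= t for s in instance.family):
                w = instance.witness_weight(chosen)
                key = (w, combo)
                if best_key is None or _cmp_subsolutions(key, best_key) < 0:
                    best = chosen
                    best_key = key
    assert best is not None
    return CoverSolution(
        frozenset(best), instance.witness_weight(best), hit_vector(best, instance)
    )


# ---------------------------------------------------------------------------
# analytic complexity bounds


def effective_base(t: int, d: int) -> float:
    """Effective exponential base ``(t+1)^(d/(d+log2(t+1)))``.

    This replaces ``t+1`` in the worst-case state-count bound when enough
    subsets have size at most ``d``; it lies strictly between 1 and ``t+1``
    and increases with ``d``.
    """
    if t < 1 or d < 1:
        raise ValueError("t and d must be >= 1")
    return float((t + 1) ** (d / (d + math.log2(t + 1))))


def speedup_bound(t: int, d: int, n: int) -> float:
    """Worst-case speedup ``((t+1)/effective_base(t, d))^n`` over the plain
    ``(t+1)^n`` dynamic program at ``n`` subsets."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(((t + 1) / effective_base(t, d)) ** n)
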