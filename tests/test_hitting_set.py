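"""Unit and property tests for the exact t-cover hitting set solver."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from tfcover import (
    HittingSetInstance,
    InfeasibleInstanceError,
    brute_force_t_cover,
    effective_base,
    hit_vector,
    solve_weighted_t_cover,
    sort_instance,
    speedup_bound,
)
from tfcover.hitting_set import SolverStats

from conftest import random_instance


def make(elements, weights, family, t, **kw):
    return HittingSetInstance(tuple(elements), weights, tuple(family), t, **kw)


# ---------------------------------------------------------------------------
# instance validation


class TestInstanceValidation:
    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError, match="non-positive"):
            make("ab", {"a": 0.0, "b": 1.0}, [{"a", "b"}], 1)

    def test_rejects_empty_subset(self):
        with pytest.raises(ValueError, match="non-empty"):
            make("ab", {"a": 1.0, "b": 1.0}, [frozenset()], 1)

    def test_rejects_unknown_member(self):
        with pytest.raises(ValueError, match="unknown"):
            make("ab", {"a": 1.0, "b": 1.0}, [{"a", "z"}], 1)

    def test_rejects_duplicate_elements(self):
        with pytest.raises(ValueError, match="unique"):
            HittingSetInstance(("a", "a"), {"a": 1.0}, (), 1)

    def test_dummy_may_have_zero_weight(self):
        inst = make("ad", {"a": 1.0, "d": 0.0}, [{"a", "d"}], 2,
                    dummies=frozenset("d"))
        assert inst.dummies == {"d"}


# ---------------------------------------------------------------------------
# ordering


class TestSortInstance:
    @pytest.mark.parametrize(
        "family, exp_subsets, exp_prefix",
        [
            # prefix rule with lexicographic tie-breaks
            ([{"a", "b"}, {"b", "c", "d"}],
             [{"a", "b"}, {"b", "c", "d"}], ["a", "b", "c", "d"]),
            # size sort puts the pair first
            ([{"x", "y", "z"}, {"p", "q"}],
             [{"p", "q"}, {"x", "y", "z"}], ["p", "q", "x", "y", "z"]),
            # duplicate subsets are allowed
            ([{"a"}, {"a"}], [{"a"}, {"a"}], ["a"]),
        ],
    )
    def test_examples(self, family, exp_subsets, exp_prefix):
        elements = sorted(set().union(*family))
        inst = make(elements, {e: 1.0 for e in elements},
                    [frozenset(s) for s in family], 1)
        order, fam = sort_instance(inst)
        assert [set(s) for s in fam] == exp_subsets
        assert list(order[: len(exp_prefix)]) == exp_prefix

    def test_subset_free_elements_go_last(self):
        inst = make("abz", {"a": 1, "b": 1, "z": 1}, [{"a", "b"}], 1)
        order, _ = sort_instance(inst)
        assert order == ("a", "b", "z")

    def test_prefix_property_random(self):
        rnd = random.Random(11)
        for _ in range(50):
            inst = random_instance(rnd)
            order, fam = sort_instance(inst)
            sizes = [len(s) for s in fam]
            assert sizes == sorted(sizes)
            pos = {u: i for i, u in enumerate(order)}
            union = set()
            for s in fam:
                union |= s
                # every prefix union occupies an order prefix
                assert {order[i] for i in range(len(union))} == union
            assert set(order) == set(inst.elements)
            assert all(u in pos for u in inst.elements)


class TestHitVector:
    def test_empty_witness(self):
        inst = make("abcd", dict.fromkeys("abcd", 1.0), [{"a", "b"}, {"b", "c"}], 2)
        assert hit_vector(set(), inst) == (0, 0)

    def test_direct_count(self):
        inst = make("abcd", dict.fromkeys("abcd", 1.0), [{"a", "b"}, {"b", "c"}], 2)
        assert hit_vector({"a", "b"}, inst) == (2, 1)

    def test_cap_at_t(self):
        inst = make("abcd", dict.fromkeys("abcd", 1.0), [{"a", "b"}, {"b", "c"}], 1)
        assert hit_vector({"a", "b", "c"}, inst) == (1, 1)

    def test_unknown_element_rejected(self):
        inst = make("ab", {"a": 1.0, "b": 1.0}, [{"a"}], 1)
        with pytest.raises(ValueError, match="unknown"):
            hit_vector({"z"}, inst)


# ---------------------------------------------------------------------------
# solver


class TestSolver:
    def test_singleton(self):
        inst = make("a", {"a": 1.0}, [{"a"}], 1)
        (sol,) = solve_weighted_t_cover(inst)
        assert sol.witness == {"a"} and sol.weight == 1.0

    def test_shared_element_optimum(self):
        inst = make("abc", dict.fromkeys("abc", 1.0), [{"a", "b"}, {"b", "c"}], 1)
        sol = solve_weighted_t_cover(inst)[0]
        assert sol.witness == {"b"} and sol.weight == 1.0

    def test_weighted_optimum_avoids_heavy_element(self):
        inst = make("abcd", {"a": 1, "b": 1, "c": 1, "d": 10},
                    [{"a", "b", "d"}, {"b", "c", "d"}], 2)
        sol = solve_weighted_t_cover(inst)[0]
        assert sol.witness == {"a", "b", "c"}
        assert sol.weight == pytest.approx(3.0)

    def test_infeasible_subset_named(self):
        inst = make("ab", {"a": 1.0, "b": 1.0}, [{"a"}], 2)
        with pytest.raises(InfeasibleInstanceError, match="a"):
            solve_weighted_t_cover(inst)

    def test_empty_family_vacuous(self):
        inst = make("ab", {"a": 1.0, "b": 1.0}, [], 2)
        with pytest.warns(UserWarning, match="vacuously"):
            (sol,) = solve_weighted_t_cover(inst)
        assert sol.witness == frozenset() and sol.weight == 0.0

    def test_coverage_reported_in_input_family_order(self):
        inst = make("abc", dict.fromkeys("abc", 1.0),
                    [{"a", "b", "c"}, {"a"}], 1)
        sol = solve_weighted_t_cover(inst)[0]
        assert sol.coverage == hit_vector(sol.witness, inst)

    def test_monotone_in_t(self):
        rnd = random.Random(23)
        for _ in range(30):
            inst = random_instance(rnd, max_t=2)
            if any(len(s) < inst.t + 1 for s in inst.family):
                continue
            w_t = solve_weighted_t_cover(inst)[0].weight
            bumped = HittingSetInstance(
                inst.elements, inst.weights, inst.family, inst.t + 1
            )
            w_t1 = solve_weighted_t_cover(bumped)[0].weight
            assert w_t1 >= w_t - 1e-9


class TestOracleEquivalence:
    def test_dp_matches_brute_force_and_state_bounds(self):
        """DP optimum equals exhaustive search on 250 random instances;
        the state store never exceeds (t+1)^n, nor the d-refined bound."""
        rnd = random.Random(1234)
        for _ in range(250):
            inst = random_instance(rnd)
            stats = SolverStats()
            dp = solve_weighted_t_cover(inst, stats=stats)[0]
            bf = brute_force_t_cover(inst)
            assert dp.weight == pytest.approx(bf.weight, abs=1e-9)
            assert all(c >= inst.t for c in dp.coverage)
            assert all(c >= inst.t for c in bf.coverage)
            n, t = inst.n, inst.t
            assert stats.max_states <= (t + 1) ** n
            d = max(len(s) for s in inst.family)
            assert stats.max_states <= effective_base(t, d) ** n * 2

    def test_brute_force_refuses_large_universe(self):
        els = tuple(f"e{i}" for i in range(21))
        inst = make(els, dict.fromkeys(els, 1.0), [set(els[:2])], 1)
        with pytest.raises(ValueError, match="brute force"):
            brute_force_t_cover(inst)

    def test_brute_force_forced_full_subset(self):
        inst = make("ab", {"a": 1.0, "b": 1.0}, [{"a", "b"}], 2)
        sol = brute_force_t_cover(inst)
        assert sol.witness == {"a", "b"} and sol.weight == pytest.approx(2.0)

    def test_brute_force_infeasible(self):
        inst = make("ab", {"a": 1.0, "b": 1.0}, [{"a"}], 2)
        with pytest.raises(InfeasibleInstanceError):
            brute_force_t_cover(inst)


class TestTopK:
    def test_topk_contract_random(self):
        """Weights non-decreasing, first is optimal, all covers valid and
        witnesses pairwise distinct."""
        rnd = random.Random(77)
        for _ in range(60):
            inst = random_instance(rnd, max_m=10, max_n=5)
            k = rnd.randint(2, 4)
            sols = solve_weighted_t_cover(inst, top_k=k)
            assert 1 <= len(sols) <= k
            weights = [s.weight for s in sols]
            assert weights == sorted(weights)
            assert weights[0] == pytest.approx(
                brute_force_t_cover(inst).weight, abs=1e-9
            )
            witnesses = {s.witness for s in sols}
            assert len(witnesses) == len(sols)
            for s in sols:
                assert all(c >= inst.t for c in s.coverage)

    def test_topk_second_best_exact(self):
        inst = make("abcd", {"a": 1, "b": 1, "c": 1, "d": 10},
                    [{"a", "b", "d"}, {"b", "c", "d"}], 2)
        sols = solve_weighted_t_cover(inst, top_k=2)
        assert sols[0].witness == {"a", "b", "c"}
        assert sols[1].witness == {"b", "d"}
        assert sols[1].weight == pytest.approx(11.0)


# ---------------------------------------------------------------------------
# hit-vector extension property (the solver's key interchangeability lemma)


@st.composite
def _hit_extension_case(draw):
    m = draw(st.integers(4, 10))
    elements = tuple(f"e{i}" for i in range(m))
    t = draw(st.integers(1, 3))
    n = draw(st.integers(1, 4))
    family = tuple(
        frozenset(draw(st.sets(st.sampled_from(elements), min_size=1, max_size=m)))
        for _ in range(n)
    )
    inst = HittingSetInstance(elements, dict.fromkeys(elements, 1.0), family, t)
    h1 = draw(st.sets(st.sampled_from(elements)))
    h2 = draw(st.sets(st.sampled_from(elements)))
    rest = [e for e in elements if e not in h1 | h2]
    hp = draw(st.sets(st.sampled_from(rest))) if rest else set()
    return inst, h1, h2, hp


@given(_hit_extension_case())
@settings(max_examples=200, derandomize=True)
def test_equal_hit_vectors_stay_equal_under_disjoint_extension(case):
    """If two witnesses hit every subset identically, any extension disjoint
    from both preserves that equality."""
    inst, h1, h2, hp = case
    if hit_vector(h1, inst) != hit_vector(h2, inst):
        return
    assert hit_vector(h1 | hp, inst) == hit_vector(h2 | hp, inst)


# ---------------------------------------------------------------------------
# analytic bounds


class TestComplexityBounds:
    @pytest.mark.parametrize("t, printed", [(2, 2.303), (3, 2.692), (4, 3.002)])
    def test_effective_base_within_printed_bound(self, t, printed):
        assert round(effective_base(t, 5), 3) <= printed

    def test_effective_base_range_and_monotonicity(self):
        for t in range(1, 6):
            prev = 1.0
            for d in range(1, 12):
                b = effective_base(t, d)
                assert 1.0 < b < t + 1
                assert b > prev
                prev = b

    @pytest.mark.parametrize("t, printed", [(2, 1393), (3, 48131), (4, 1108459)])
    def test_speedup_meets_printed_lower_bound(self, t, printed):
        assert speedup_bound(t, 5, 30) >= printed

    def test_speedup_grows_with_n(self):
        assert speedup_bound(1, 3, 1) > 1.0
        vals = [speedup_bound(2, 5, n) for n in (1, 5, 10, 20)]
        assert vals == sorted(vals) and vals[0] > 1.0

    def test_speedup_consistent_with_base(self):
        t, d, n = 3, 4, 12
        expected = ((t + 1) / effective_base(t, d)) ** n
        assert speedup_bound(t, d, n) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            effective_base(0, 5)
        with pytest.raises(ValueError):
            speedup_bound(2, 5, 0)
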