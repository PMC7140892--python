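"""Footrule distance, Borda, exhaustive oracle and Cross-Entropy optimizer."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hkgrank as hk
from hkgrank.rankagg import aggregate_borda, aggregate_ce, aggregate_exhaustive


# ------------------------------------------------------------------ footrule

def test_footrule_examples():
    assert hk.footrule_distance(["g1", "g2"], ["g1", "g2"], 2) == 0.0
    assert hk.footrule_distance(["g1", "g2", "g3"], ["g3", "g2", "g1"], 3) == 4.0
    assert hk.footrule_distance(["a", "b"], ["a", "c"], 2) == 2.0


def test_footrule_rejects_duplicates():
    with pytest.raises(ValueError):
        hk.footrule_distance(["a", "a"], ["a", "b"], 2)


@st.composite
def _klists(draw, n_items=6, k=4):
    universe = [f"g{i}" for i in range(n_items)]
    perm = draw(st.permutations(universe))
    return list(perm[:k])


@given(_klists(), _klists(), _klists())
def test_footrule_is_a_metric(a, b, c):
    d = lambda x, y: hk.footrule_distance(x, y, 4)
    assert d(a, b) == d(b, a)                       # symmetry
    assert (d(a, b) == 0) == (a == b)               # identity of indiscernibles
    assert d(a, c) <= d(a, b) + d(b, c) + 1e-12     # triangle inequality


# -------------------------------------------------------------- ce objective

def test_ce_objective_examples():
    gls = [["a", "b"], ["a", "b"]]
    assert hk.ce_objective(["a", "b"], gls, 2) == 0.0
    single = [["a", "b", "c"]]
    assert hk.ce_objective(["c", "b", "a"], single, 3) == \
        hk.footrule_distance(["c", "b", "a"], ["a", "b", "c"], 3)
    two = [["a", "b"], ["b", "c"]]
    d1 = hk.footrule_distance(["a", "c"], two[0], 2)
    d2 = hk.footrule_distance(["a", "c"], two[1], 2)
    assert hk.ce_objective(["a", "c"], two, 2) == pytest.approx((d1 + d2) / 2)
    with pytest.raises(ValueError):
        hk.ce_objective(["a"], [], 1)


# --------------------------------------------------------------------- borda

def test_borda_identical_lists_and_single_list():
    gls = [["a", "b", "c"]] * 3
    assert aggregate_borda(gls, 3).items == ["a", "b", "c"]
    assert aggregate_borda([["x", "y"]], 2).items == ["x", "y"]


def test_borda_lexicographic_tie_break():
    out = aggregate_borda([["a", "b", "c"], ["b", "a", "c"]], 3)
    assert out.items == ["a", "b", "c"]     # a,b tie at mean rank 1.5


# ---------------------------------------------------------------- exhaustive

def brute_force_best(gls, k):
    """Independent enumeration (second implementation for cross-checking)."""
    universe = sorted({g for gl in gls for g in gl})
    best, best_obj = None, float("inf")
    for combo in itertools.permutations(universe, k):
        obj = float(np.mean([hk.footrule_distance(list(combo), gl, k)
                             for gl in gls]))
        if obj < best_obj - 1e-12:
            best, best_obj = list(combo), obj
    return best, best_obj


def test_exhaustive_single_list_is_that_list():
    out = aggregate_exhaustive([["a", "b", "c"]], 3)
    assert out.items == ["a", "b", "c"] and out.objective == 0.0


def test_exhaustive_matches_independent_brute_force(rng):
    universe = ["a", "b", "c", "d"]
    gls = [list(rng.permutation(universe)[:2]) for _ in range(3)]
    out = aggregate_exhaustive(gls, 2)
    bf_items, bf_obj = brute_force_best(gls, 2)
    assert out.objective == pytest.approx(bf_obj)
    assert out.items == bf_items


def test_exhaustive_beats_or_matches_borda(rng):
    for _ in range(5):
        universe = [f"g{i}" for i in range(5)]
        gls = [list(rng.permutation(universe)[:3]) for _ in range(4)]
        assert aggregate_exhaustive(gls, 3).objective <= \
            aggregate_borda(gls, 3).objective + 1e-12


def test_exhaustive_cap():
    gls = [[f"g{i}" for i in range(12)]]
    with pytest.raises(ValueError, match="cap"):
        aggregate_exhaustive(gls, 8, cap=100)


# ------------------------------------------------------------- cross-entropy

def test_ce_identical_inputs_returns_them_with_zero_objective():
    gls = [["a", "b", "c", "d"]] * 4
    out = aggregate_ce(gls, 4, seed=0)
    assert out.items == ["a", "b", "c", "d"]
    assert out.objective == 0.0


def test_ce_attains_exhaustive_optimum_on_small_instances():
    rng = np.random.default_rng(99)
    hits = 0
    for inst in range(10):
        universe = [f"g{i}" for i in range(6)]
        gls = [list(rng.permutation(universe)[:4]) for _ in range(5)]
        ex = aggregate_exhaustive(gls, 4)
        ce = aggregate_ce(gls, 4, seed=inst)
        hits += ce.objective <= ex.objective + 1e-12
    assert hits >= 9


def test_ce_disjoint_lists_not_worse_than_either_input():
    gls = [["a", "b", "c"], ["d", "e", "f"]]
    out = aggregate_ce(gls, 3, seed=5)
    for gl in gls:
        assert out.objective <= hk.ce_objective(gl, gls, 3) + 1e-12


def test_ce_trace_is_monotone_and_seed_reproducible(rng):
    universe = [f"g{i}" for i in range(8)]
    gls = [list(rng.permutation(universe)[:5]) for _ in range(6)]
    a = aggregate_ce(gls, 5, seed=7)
    b = aggregate_ce(gls, 5, seed=7)
    assert a.items == b.items and a.objective == b.objective
    trace = a.diagnostics["trace"]
    assert all(t2 <= t1 + 1e-12 for t1, t2 in zip(trace, trace[1:]))
    assert a.diagnostics["converged"] in (True, False)


def test_ce_parameter_validation():
    gls = [["a", "b"]]
    with pytest.raises(ValueError):
        aggregate_ce(gls, 3, seed=0)            # k exceeds universe
    with pytest.raises(ValueError):
        aggregate_ce(gls, 2, rho=1.5, seed=0)
    with pytest.raises(ValueError):
        aggregate_ce([], 1, seed=0)


def test_ce_universe_gate_engages_only_at_scale(rng):
    # 150 items, half supported by most lists -> gate trims the universe
    universe = [f"g{i:03d}" for i in range(150)]
    core = universe[:30]
    gls = [list(rng.permutation(core)[:20]) +
           list(rng.permutation(universe[30:])[:15]) for _ in range(8)]
    assert len({g for gl in gls for g in gl}) > 100   # gate precondition
    out = aggregate_ce(gls, 10, seed=0, max_iter=30)
    assert out.diagnostics["universe_size"] < 100
    # small instances: union is the universe
    small = aggregate_ce([["a", "b", "c"]], 2, seed=0)
    assert small.diagnostics["universe_size"] == 3
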