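"""Rank aggregation of many ordered gene lists into one top-K consensus list.

The objective is the mean Spearman footrule distance between a candidate
ordered list and each input list, with items absent from a top-k list
assigned rank k+1.  The production optimizer is a Cross-Entropy Monte Carlo
search over ordered k-lists; a Borda (mean-rank) heuristic and an exhaustive
enumerator serve as initializer and oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class AggregatedList:
    """Top-K consensus list for one track, with optimizer diagnostics."""

    track: str
    items: list[str]
    objective: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("aggregated list contains duplicates")
        if self.objective < 0:
            raise ValueError("objective must be non-negative")


def _check_no_duplicates(lst, name: str) -> None:
    if len(set(lst)) != len(lst):
        raise ValueError(f"{name} contains duplicate items")


def footrule_distance(candidate, reference, k: int | None = None) -> float:
    """Spearman footrule between two top-k ordered lists.

    Over the union of items, rank = 1-based position if present, else k+1;
    the distance is the L1 difference of the two rank assignments.  Zero iff
    the lists are identical as ordered lists of length k.
    """
    candidate = list(candidate)
    reference = list(reference)
    _check_no_duplicates(candidate, "candidate")
    _check_no_duplicates(reference, "reference")
    if k is None:
        k = max(len(candidate), len(reference))
    rc = {g: i + 1 for i, g in enumerate(candidate)}
    rr = {g: i + 1 for i, g in enumerate(reference)}
    union = set(candidate) | set(reference)
    return float(sum(abs(rc.get(g, k + 1) - rr.get(g, k + 1)) for g in union))


def ce_objective(candidate, gls, k: int) -> float:
    """Unweighted mean footrule distance from a candidate to the input lists."""
    if not gls:
        raise ValueError("need at least one input list")
    return float(np.mean([footrule_distance(candidate, gl, k) for gl in gls]))


def _universe(gls) -> list[str]:
    seen: dict[str, None] = {}
    for gl in gls:
        for g in gl:
            seen.setdefault(g, None)
    return sorted(seen)


def _rank_matrix(gls, universe: list[str], k: int) -> np.ndarray:
    """(n_lists, |universe|) integer rank matrix with absent rank k+1."""
    pos = {g: i for i, g in enumerate(universe)}
    ranks = np.full((len(gls), len(universe)), k + 1, dtype=np.int64)
    for i, gl in enumerate(gls):
        for r, g in enumerate(gl, start=1):
            ranks[i, pos[g]] = r
    return ranks


def aggregate_borda(gls, k: int, track: str = "") -> AggregatedList:
    """Mean-rank (Borda) aggregation: ascending mean assigned rank, ties
    broken lexicographically by item id."""
    for gl in gls:
        _check_no_duplicates(gl, "input list")
    universe = _universe(gls)
    if k > len(universe):
        raise ValueError("k exceeds the candidate universe")
    ranks = _rank_matrix(gls, universe, k)
    mean_rank = ranks.mean(axis=0)
    order = np.lexsort((np.array(universe), mean_rank))[:k]
    items = [universe[i] for i in order]
    return AggregatedList(track, items, ce_objective(items, gls, k),
                          {"method": "borda"})


def aggregate_exhaustive(gls, k: int, cap: int = 50_000,
                         track: str = "") -> AggregatedList:
    """Globally optimal aggregation by enumerating all ordered k-lists.

    Ties are broken deterministically: the lexicographically first optimal
    list (in enumeration order over the sorted universe) is returned.
    """
    for gl in gls:
        _check_no_duplicates(gl, "input list")
    universe = _universe(gls)
    if k > len(universe):
        raise ValueError("k exceeds the candidate universe")
    n_lists = math.perm(len(universe), k)
    if n_lists > cap:
        raise ValueError(f"{n_lists} ordered {k}-lists exceed the cap of {cap}")
    ranks = _rank_matrix(gls, universe, k)
    best_items, best_obj = None, np.inf
    for combo in itertools.permutations(range(len(universe)), k):
        cand = np.full(len(universe), k + 1, dtype=np.int64)
        cand[list(combo)] = np.arange(1, k + 1)
        obj = np.abs(ranks - cand[None, :]).sum(axis=1).mean()
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_items = [universe[i] for i in combo]
    return AggregatedList(track, best_items, float(best_obj),
                          {"method": "exhaustive", "n_evaluated": n_lists})


def aggregate_ce(
    gls,
    k: int,
    n_samples: int | None = None,
    rho: float = 0.1,
    nu: float = 0.7,
    max_iter: int = 500,
    conv_window: int = 15,
    seed: int | np.random.SeedSequence = 0,
    track: str = "",
    init: str = "borda",
    min_support_frac: float = 0.5,
    gate_min_universe: int = 100,
) -> AggregatedList:
    """Cross-Entropy Monte Carlo aggregation.

    Maintains a k x |universe| position-probability matrix; each iteration
    samples ``n_samples`` duplicate-free ordered lists position-by-position
    with renormalization, scores them with the mean footrule objective, takes
    the ``rho``-quantile elite and updates the probabilities with
    ``nu``-smoothed elite frequencies.  Stops when the best objective has not
    improved for ``conv_window`` iterations (converged) or at ``max_iter``.

    For large problems the universe is first gated to items appearing in at
    least ``min_support_frac`` of the input lists; the gate only engages when
    the union exceeds ``gate_min_universe`` items, so it is a no-op at desk
    scale.
    """
    if not gls:
        raise ValueError("need at least one input list")
    for gl in gls:
        _check_no_duplicates(gl, "input list")
    for name, v in (("rho", rho), ("nu", nu)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    universe = _universe(gls)
    if len(universe) > gate_min_universe:
        support = {g: 0 for g in universe}
        for gl in gls:
            for g in gl:
                support[g] += 1
        need = min_support_frac * len(gls)
        gated = [g for g in universe if support[g] >= need]
        if len(gated) < k + 10:  # never gate below a workable search space
            by_support = sorted(universe, key=lambda g: (-support[g], g))
            gated = sorted(by_support[:min(len(universe), k + 10)])
        universe = gated
    U = len(universe)
    if k > U:
        raise ValueError("k exceeds the candidate universe")
    if n_samples is None:
        n_samples = min(10 * k * U, 5000)

    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(universe)}
    ref_ranks = _rank_matrix([[g for g in gl if g in pos] for gl in gls],
                             universe, k)

    def score_rows(S: np.ndarray) -> np.ndarray:
        R = np.full((S.shape[0], U), k + 1, dtype=np.int64)
        R[np.arange(S.shape[0])[:, None], S] = np.arange(1, k + 1)[None, :]
        acc = np.zeros(S.shape[0])
        for g_ranks in ref_ranks:
            acc += np.abs(R - g_ranks[None, :]).sum(axis=1)
        return acc / len(ref_ranks)

    # initial probability matrix, optionally biased 3:1 toward Borda positions
    borda = aggregate_borda(gls, k)
    p = np.full((k, U), 1.0 / U)
    if init == "borda":
        p = np.ones((k, U))
        for t, g in enumerate(borda.items):
            if g in pos:
                p[t, pos[g]] = 3.0
        p /= p.sum(axis=1, keepdims=True)
    elif init != "uniform":
        raise ValueError("init must be 'borda' or 'uniform'")

    # seed best-so-far with the Borda list and the (truncated) inputs
    best_items = borda.items
    best_obj = borda.objective
    for gl in gls:
        cand = [g for g in gl if g in pos][:k]
        if len(cand) == k:
            obj = ce_objective(cand, gls, k)
            if obj < best_obj - 1e-12:
                best_obj, best_items = obj, list(cand)

    trace = []
    stall = 0
    converged = False
    n_elite = max(1, math.ceil(rho * n_samples))
    iterations = 0
    for iterations in range(1, max_iter + 1):
        S = np.empty((n_samples, k), dtype=np.int64)
        avail = np.ones((n_samples, U), dtype=bool)
        rows = np.arange(n_samples)
        for t in range(k):
            w = p[t][None, :] * avail
            wsum = w.sum(axis=1, keepdims=True)
            w = np.where(wsum > 0, w, avail.astype(float))
            cdf = np.cumsum(w, axis=1)
            r = rng.random((n_samples, 1)) * cdf[:, -1:]
            idx = (r > cdf).sum(axis=1)
            S[:, t] = idx
            avail[rows, idx] = False
        obj = score_rows(S)
        elite = np.argpartition(obj, n_elite - 1)[:n_elite]
        it_best = int(elite[np.argmin(obj[elite])])
        if obj[it_best] < best_obj - 1e-12:
            best_obj = float(obj[it_best])
            best_items = [universe[i] for i in S[it_best]]
            stall = 0
        else:
            stall += 1
        trace.append(best_obj)
        if stall >= conv_window:
            converged = True
            break
        freq = np.empty((k, U))
        for t in range(k):
            freq[t] = np.bincount(S[elite, t], minlength=U)
        p = nu * freq / n_elite + (1.0 - nu) * p

    seed_repr = seed if isinstance(seed, int) else "seedsequence"
    return AggregatedList(
        track, best_items, best_obj,
        {
            "method": "cross-entropy",
            "iterations": iterations,
            "converged": converged,
            "seed": seed_repr,
            "n_samples": n_samples,
            "universe_size": U,
            "trace": trace,
        },
    )
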