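"""Dynamic programming over the local score: the optimal alignment A_L and
a pool of suboptimal candidates that seed the local search.

The DP minimizes the UNNORMALIZED local score (sum of weighted positional
match costs plus the affine gap penalty); normalization by match-state size
makes the objective non-decomposable, so A_L is defined on the raw score
and the normalized value is reported alongside for the theta gate.

The three-state recursion (match / template-gap / query-gap) works on the
canonical gapped form in which, inside each inter-match block, template-gap
columns precede query-gap columns — matching the gap-count convention of
:func:`pdthread.alignment_core.count_gaps` exactly, including the free-end
flags.

"Best 100 from the DP table" is realized as Boltzmann-weighted stochastic
traceback at a fixed temperature over a soft-min version of the same
tables, seeded and deduplicated; the exact optimum is always the first
candidate.
"""
from __future__ import annotations

import math
from typing import Callable, List, Tuple

import numpy as np

from .alignment_core import AlignmentMapping, from_match_states
from .io_models import QueryProfile, Template
from .local_scoring import (LocalWeights, identity_cle_matrix,
                            position_cost_matrix)

INF = math.inf


def _gap_run_cost(length: int, w_go: float, w_ge: float) -> float:
    return 0.0 if length == 0 else w_go + length * w_ge


def _end_cost(dels: int, ins: int, w_go: float, w_ge: float,
              free_query_ends: bool, free_template_ends: bool) -> float:
    c = 0.0
    if not free_template_ends:
        c += _gap_run_cost(dels, w_go, w_ge)
    if not free_query_ends:
        c += _gap_run_cost(ins, w_go, w_ge)
    return c


def raw_score_of_matches(pairs, cost: np.ndarray, weights: LocalWeights,
                         m: int, n: int, free_query_ends: bool,
                         free_template_ends: bool) -> float:
    """Raw local score of the alignment with the given match-state list,
    computed from the positional cost matrix (brute-force oracle path)."""
    w_go, w_ge = weights.w_go, weights.w_ge
    total = 0.0
    pt, ps = 0, 0
    blocks = []
    for (t, s) in list(pairs) + [(m + 1, n + 1)]:
        blocks.append((t - pt - 1, s - ps - 1))
        if t <= m:
            total += cost[t - 1, s - 1]
        pt, ps = t, s
    last = len(blocks) - 1
    for i, (dels, ins) in enumerate(blocks):
        if i == 0 or i == last:
            total += _end_cost(dels, ins, w_go, w_ge,
                               free_query_ends, free_template_ends)
        else:
            total += _gap_run_cost(dels, w_go, w_ge)
            total += _gap_run_cost(ins, w_go, w_ge)
    return total


def _fill_tables(cost: np.ndarray, weights: LocalWeights,
                 free_query_ends: bool, free_template_ends: bool,
                 reduce3: Callable = min):
    """Fill the M / X / Y tables with a pluggable reducer (min for the
    optimum, a soft-min for Boltzmann sampling). Indices are 1-based; state
    (i, j) means template 1..i and query 1..j consumed."""
    m, n = cost.shape
    w_go, w_ge = weights.w_go, weights.w_ge
    opn = w_go + w_ge
    M = np.full((m + 1, n + 1), INF)
    X = np.full((m + 1, n + 1), INF)
    Y = np.full((m + 1, n + 1), INF)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            lead = _end_cost(i - 1, j - 1, w_go, w_ge,
                             free_query_ends, free_template_ends)
            M[i, j] = cost[i - 1, j - 1] + reduce3(
                (lead, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            X[i, j] = reduce3((M[i - 1, j] + opn, X[i - 1, j] + w_ge))
            Y[i, j] = reduce3((M[i, j - 1] + opn, X[i, j - 1] + opn,
                               Y[i, j - 1] + w_ge))
    return M, X, Y


def _empty_cost(m: int, n: int, weights: LocalWeights,
                free_query_ends: bool, free_template_ends: bool) -> float:
    return _end_cost(m, n, weights.w_go, weights.w_ge,
                     free_query_ends, free_template_ends)


def dp_optimal(template: Template, query: QueryProfile,
               weights: LocalWeights,
               cle_matrix=identity_cle_matrix,
               free_query_ends: bool = True,
               free_template_ends: bool = False
               ) -> Tuple[AlignmentMapping, float, float]:
    """The raw-score minimizer A_L with its raw and normalized scores.

    Tie-breaking during traceback is deterministic: prefer match, then
    template-gap, then query-gap, and among equally scoring end points the
    lexicographically smallest (i, j).
    """
    cost = position_cost_matrix(template, query, weights, cle_matrix)
    m, n = cost.shape
    M, X, Y = _fill_tables(cost, weights, free_query_ends,
                           free_template_ends)
    w_go, w_ge = weights.w_go, weights.w_ge
    opn = w_go + w_ge

    best = _empty_cost(m, n, weights, free_query_ends, free_template_ends)
    end = None
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            v = M[i, j] + _end_cost(m - i, n - j, w_go, w_ge,
                                    free_query_ends, free_template_ends)
            if v < best:
                best, end = v, (i, j)
    if end is None:
        a = from_match_states([], m, n)
        return a, best, INF

    def argmin_pref(options):
        """Index of the minimum, first occurrence wins (preference order)."""
        best_k, best_v = 0, options[0]
        for k, v in enumerate(options[1:], start=1):
            if v < best_v:
                best_k, best_v = k, v
        return best_k

    pairs = []
    i, j = end
    state = "M"
    while True:
        if state == "M":
            pairs.append((i, j))
            lead = _end_cost(i - 1, j - 1, w_go, w_ge,
                             free_query_ends, free_template_ends)
            k = argmin_pref([M[i - 1, j - 1], X[i - 1, j - 1],
                             Y[i - 1, j - 1], lead])
            if k == 3:
                break
            state = "MXY"[k]
            i, j = i - 1, j - 1
        elif state == "X":
            k = argmin_pref([M[i - 1, j] + opn, X[i - 1, j] + w_ge])
            state = "MX"[k]
            i -= 1
        else:
            k = argmin_pref([M[i, j - 1] + opn, X[i, j - 1] + opn,
                             Y[i, j - 1] + w_ge])
            state = "MXY"[k]
            j -= 1
    pairs.reverse()
    a = from_match_states(pairs, m, n)
    return a, best, best / len(pairs)


def _softmin_factory(temperature: float):
    def softmin(vals):
        arr = np.array([v for v in vals if v < INF])
        if arr.size == 0:
            return INF
        lo = arr.min()
        return lo - temperature * math.log(
            np.exp(-(arr - lo) / temperature).sum())
    return softmin


def _boltzmann_pick(rng, options, temperature: float) -> int:
    """Index sampled with probability proportional to exp(-value / T)."""
    vals = np.array(options, dtype=float)
    finite = np.isfinite(vals)
    w = np.zeros(len(vals))
    lo = vals[finite].min()
    w[finite] = np.exp(-(vals[finite] - lo) / temperature)
    return int(rng.choice(len(vals), p=w / w.sum()))


def dp_candidates(template: Template, query: QueryProfile,
                  weights: LocalWeights, count: int = 100, seed: int = 0,
                  temperature: float = 1.0, oversample: int = 8,
                  cle_matrix=identity_cle_matrix,
                  free_query_ends: bool = True,
                  free_template_ends: bool = False
                  ) -> List[Tuple[AlignmentMapping, float]]:
    """Up to `count` distinct alignments best-first by raw local score; the
    first entry is always the exact optimum. Reproducible under `seed`."""
    if count < 1:
        raise ValueError("count must be >= 1")
    cost = position_cost_matrix(template, query, weights, cle_matrix)
    m, n = cost.shape
    w_go, w_ge = weights.w_go, weights.w_ge
    opn = w_go + w_ge
    softmin = _softmin_factory(temperature)
    M, X, Y = _fill_tables(cost, weights, free_query_ends,
                           free_template_ends, reduce3=softmin)
    rng = np.random.default_rng(seed)

    ends = [(i, j) for i in range(1, m + 1) for j in range(1, n + 1)]
    end_vals = [M[i, j] + _end_cost(m - i, n - j, w_go, w_ge,
                                    free_query_ends, free_template_ends)
                for (i, j) in ends]
    ends.append(None)  # the all-gap alignment
    end_vals.append(_empty_cost(m, n, weights, free_query_ends,
                                free_template_ends))

    def sample_path():
        pick = _boltzmann_pick(rng, end_vals, temperature)
        if ends[pick] is None:
            return ()
        i, j = ends[pick]
        pairs = [(i, j)]
        state = "M"
        while True:
            if state == "M":
                lead = _end_cost(i - 1, j - 1, w_go, w_ge,
                                 free_query_ends, free_template_ends)
                opts = [lead, M[i - 1, j - 1], X[i - 1, j - 1],
                        Y[i - 1, j - 1]]
                k = _boltzmann_pick(rng, opts, temperature)
                if k == 0:
                    break
                state = "MXY"[k - 1]
                i, j = i - 1, j - 1
            elif state == "X":
                k = _boltzmann_pick(
                    rng, [M[i - 1, j] + opn, X[i - 1, j] + w_ge], temperature)
                state = "MX"[k]
                i -= 1
            else:
                k = _boltzmann_pick(
                    rng, [M[i, j - 1] + opn, X[i, j - 1] + opn,
                          Y[i, j - 1] + w_ge], temperature)
                state = "MXY"[k]
                j -= 1
            if state == "M":
                pairs.append((i, j))
        return tuple(sorted(pairs))

    opt, opt_raw, _ = dp_optimal(template, query, weights, cle_matrix,
                                 free_query_ends, free_template_ends)
    seen = {opt.map}
    pool = {}
    for _ in range(count * oversample):
        pairs = sample_path()
        a = from_match_states(pairs, m, n)
        if a.map in seen:
            continue
        seen.add(a.map)
        raw = raw_score_of_matches(pairs, cost, weights, m, n,
                                   free_query_ends, free_template_ends)
        pool[a.map] = (a, raw)
        if len(pool) >= count * 2:
            break
    others = sorted(pool.values(), key=lambda ar: (ar[1], ar[0].map))
    return ([(opt, opt_raw)] + others)[:count]
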