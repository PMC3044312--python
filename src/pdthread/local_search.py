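"""k-neighborhood local search over alignments and the threading driver.

The k-neighborhood N(A, k) contains every valid alignment A' for which a
set U of at most k query positions (including the left-gap sentinel 0)
exists with A'(t) in {A(t)} union U for all t — equivalently, the values
taken by A' where it differs from A number at most k. Nesting
N(A, k) subset-of N(A, k + 1) and full coverage N(A, n + 1) = F follow
directly, and |N(A, k)| is polynomial in m and n for fixed k.

The search (accept A_{i+1} only when (1 + alpha) * score(A_{i+1}) <
score(A_i)) assumes positive scores; realistic scores are negative, so the
multiplicative test is applied to shifted scores  score + score_shift  with
the shift derived from a cheap per-instance lower bound. alpha = 0 is
unaffected by the shift and yields an exact local optimum.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from math import comb
from typing import Callable, Iterator, List, Optional, Set, Tuple

import numpy as np

from .alignment_core import (AlignmentMapping, enumerate_all_alignments,
                             match_states, require_valid)
from .dp_aligner import dp_candidates, dp_optimal
from .global_energy import (DEFAULT_MIN_SEPARATION, PairPotentialTable,
                            global_score)
from .io_models import QueryProfile, Template
from .local_scoring import (LocalWeights, ScoreBreakdown, identity_cle_matrix,
                            local_score, position_cost_matrix,
                            score_breakdown)

DEFAULT_THETA = -87.0
DEFAULT_OMEGA_L = 0.0047


class ValidationError(ValueError):
    pass


@dataclass
class SearchParams:
    """Parameters of the local search: acceptance slack alpha >= 0,
    neighborhood size k >= 1, an iteration cap, and the positivity shift
    applied before the multiplicative acceptance test."""

    alpha: float = 0.01
    k: int = 1
    max_iterations: int = 1000
    score_shift: float = 0.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.k < 1:
            raise ValidationError("k must be >= 1")


def _k1_neighborhood(a: AlignmentMapping) -> Set[Tuple[int, ...]]:
    """Exact 1-neighborhood without enumerating the whole space: for each
    candidate value u, the positions rerouted to u form a contiguous
    interval bounded by the retained prefix/suffix values."""
    m, n = a.m, a.n
    base = a.map
    out = {base}
    for u in range(n + 1):
        for i in range(m):                    # interval start, 0-based
            if i > 0 and base[i - 1] > u:
                continue
            for j in range(i, m):             # interval end inclusive
                if j < m - 1 and base[j + 1] < u:
                    continue
                out.add(base[:i] + (u,) * (j - i + 1) + base[j + 1:])
    return out


def _per_value_set_neighborhood(a: AlignmentMapping,
                                values: Tuple[int, ...]) -> Iterator[Tuple]:
    """All valid maps with A'(t) in {A(t)} union values, via monotone DFS."""
    m = a.m
    base = a.map
    stack = [((), 0, 0)]  # (prefix, t, min allowed value)
    while stack:
        prefix, t, lo = stack.pop()
        if t == m:
            yield prefix
            continue
        opts = {base[t]} | set(values)
        for v in sorted(opts, reverse=True):
            if v >= lo:
                stack.append((prefix + (v,), t + 1, v))


def neighborhood(a: AlignmentMapping, k: int) -> List[AlignmentMapping]:
    """The exact k-neighborhood N(A, k), each member once, including A."""
    require_valid(a)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k == 1:
        maps = _k1_neighborhood(a)
    else:
        kk = min(k, a.n + 1)
        maps = {a.map}
        for values in itertools.combinations(range(a.n + 1), kk):
            maps.update(_per_value_set_neighborhood(a, values))
    return [AlignmentMapping(a.m, a.n, mp) for mp in sorted(maps)]


def neighborhood_oracle(a: AlignmentMapping, k: int, m: int, n: int
                        ) -> Set[Tuple[int, ...]]:
    """Brute-force ground truth: filter the full alignment space by the
    defining predicate (the values where A' differs from A number <= k).
    Test-only; refuses instances beyond the enumeration guard."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    out = set()
    for cand in enumerate_all_alignments(m, n):
        new_values = {v for v, w in zip(cand.map, a.map) if v != w}
        if len(new_values) <= k:
            out.add(cand.map)
    return out


def local_search_with_trace(
    a0: AlignmentMapping, score_fn: Callable[[AlignmentMapping], float],
    params: SearchParams,
) -> Tuple[AlignmentMapping, List[float]]:
    """Algorithm: repeatedly move to the neighborhood argmin while the
    shifted score satisfies the strict (1 + alpha) decrease test. Returns
    the final alignment and the trajectory of accepted (unshifted) scores,
    starting with score(a0). Ties in the neighborhood argmin are broken
    toward the lexicographically smallest mapping."""
    require_valid(a0)
    cur = a0
    cur_score = score_fn(a0)
    if not math.isfinite(cur_score):
        raise ValidationError("score of the initial alignment is not finite")
    trace = [cur_score]
    shift = params.score_shift
    for _ in range(params.max_iterations):
        best, best_score = None, math.inf
        for cand in neighborhood(cur, params.k):
            s = score_fn(cand)
            if s < best_score or (s == best_score and best is not None
                                  and cand.map < best.map):
                best, best_score = cand, s
        if (1.0 + params.alpha) * (best_score + shift) < cur_score + shift:
            cur, cur_score = best, best_score
            trace.append(cur_score)
        else:
            break
    return cur, trace


def local_search(a0: AlignmentMapping, score_fn, params: SearchParams
                 ) -> AlignmentMapping:
    return local_search_with_trace(a0, score_fn, params)[0]


# --------------------------------------------------------------------------
# threading driver

@dataclass
class ThreadResult:
    alignment: AlignmentMapping
    breakdown: ScoreBreakdown
    provenance: str                      # "easy" or "searched"
    dp_alignment: AlignmentMapping       # A_L
    dp_local_score: float                # normalized L(A_L)
    candidates_used: int = 0
    score_shift: float = 0.0


def score_lower_bound(template: Template, query: QueryProfile,
                      weights: LocalWeights, table: PairPotentialTable,
                      omega_l: float,
                      cle_matrix=identity_cle_matrix) -> float:
    """Cheap per-instance lower bound on omega_L * L(A) + G(A): the sum of
    negative per-position cost minima bounds the raw (hence normalized)
    local part; the table minimum times the maximal number of qualifying
    atom pairs bounds the energy."""
    cost = position_cost_matrix(template, query, weights, cle_matrix)
    lb_local = float(np.minimum(cost.min(axis=1), 0.0).sum())
    max_atoms = 5 * min(template.m, query.n)
    lb_energy = table.min_energy() * comb(max_atoms, 2)
    return omega_l * min(lb_local, 0.0) + lb_energy


def combined_score_fn(template: Template, query: QueryProfile,
                      weights: LocalWeights, table: PairPotentialTable,
                      omega_l: float,
                      min_separation: int = DEFAULT_MIN_SEPARATION,
                      cle_matrix=identity_cle_matrix,
                      free_query_ends: bool = True,
                      free_template_ends: bool = False):
    """score(A) = omega_L * L(A) + G(A) on normalized items; +inf for
    alignments without match states."""
    def fn(a: AlignmentMapping) -> float:
        l = local_score(a, template, query, weights, cle_matrix,
                        free_query_ends, free_template_ends)
        if not math.isfinite(l):
            return math.inf
        g = global_score(a, template, query, table, min_separation)
        return omega_l * l + g
    return fn


def fast_combined_score_fn(template: Template, query: QueryProfile,
                           weights: LocalWeights,
                           table: PairPotentialTable, omega_l: float,
                           min_separation: int = DEFAULT_MIN_SEPARATION,
                           cle_matrix=identity_cle_matrix,
                           free_query_ends: bool = True,
                           free_template_ends: bool = False):
    """Same objective as :func:`combined_score_fn` but with the energy
    evaluated through a precomputed :class:`AlignmentEnergyModel` and a
    score cache — the form the search driver uses."""
    from .dp_aligner import raw_score_of_matches
    from .global_energy import AlignmentEnergyModel
    cost = position_cost_matrix(template, query, weights, cle_matrix)
    model = AlignmentEnergyModel(template, query.sequence, table,
                                 min_separation)
    cache = {}

    def fn(a: AlignmentMapping) -> float:
        v = cache.get(a.map)
        if v is None:
            pairs = match_states(a)
            if not pairs:
                v = math.inf
            else:
                size = len(pairs)
                raw = raw_score_of_matches(pairs, cost, weights, a.m, a.n,
                                           free_query_ends,
                                           free_template_ends)
                v = omega_l * raw / size + model.energy(pairs) / size
            cache[a.map] = v
        return v
    return fn


def thread(query: QueryProfile, template: Template,
           theta: float = DEFAULT_THETA,
           omega_l: float = DEFAULT_OMEGA_L,
           params: Optional[SearchParams] = None,
           table: Optional[PairPotentialTable] = None,
           weights: Optional[LocalWeights] = None,
           candidates: int = 100, seed: int = 0,
           min_separation: int = DEFAULT_MIN_SEPARATION,
           cle_matrix=identity_cle_matrix,
           free_query_ends: bool = True,
           free_template_ends: bool = False) -> ThreadResult:
    """The threading driver.

    1. Compute A_L (and up to `candidates` suboptimal seeds) by dynamic
       programming on the local score.
    2. If the normalized L(A_L) < theta the pair is "easy": return A_L.
    3. Otherwise run the local search from every seed under
       score(A) = omega_L * L(A) + G(A) and return the best result
       (ties broken by the lexicographically smallest mapping).
    """
    params = params or SearchParams()
    weights = weights or LocalWeights()
    if table is None:
        table = PairPotentialTable.zeros()

    cand = dp_candidates(template, query, weights, count=candidates,
                         seed=seed, cle_matrix=cle_matrix,
                         free_query_ends=free_query_ends,
                         free_template_ends=free_template_ends)
    a_l, _raw, l_norm = dp_optimal(template, query, weights, cle_matrix,
                                   free_query_ends, free_template_ends)

    def make_breakdown(a):
        g = global_score(a, template, query, table, min_separation)
        return score_breakdown(a, template, query, weights, omega_l, g,
                               cle_matrix, free_query_ends,
                               free_template_ends)

    if l_norm < theta:
        return ThreadResult(a_l, make_breakdown(a_l), "easy", a_l, l_norm)

    score_fn = fast_combined_score_fn(template, query, weights, table,
                                      omega_l, min_separation, cle_matrix,
                                      free_query_ends, free_template_ends)
    shift = 1.0 - score_lower_bound(template, query, weights, table,
                                    omega_l, cle_matrix)
    sp = SearchParams(params.alpha, params.k, params.max_iterations, shift)
    best, best_score = None, math.inf
    used = 0
    for a0, _ in cand:
        if not math.isfinite(score_fn(a0)):
            continue
        used += 1
        res, trace = local_search_with_trace(a0, score_fn, sp)
        s = trace[-1]
        if s < best_score or (s == best_score and best is not None
                              and res.map < best.map):
            best, best_score = res, s
    if best is None:  # no candidate had a finite score; fall back to A_L
        best = a_l
    return ThreadResult(best, make_breakdown(best), "searched", a_l, l_norm,
                        candidates_used=used, score_shift=shift)
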