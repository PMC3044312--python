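"""k-neighborhood semantics, the local search guarantees, and the
threading driver."""
import math

import numpy as np
import pytest

from pdthread.alignment_core import (AlignmentMapping, alignment_accuracy,
                                     enumerate_all_alignments, match_states)
from pdthread.dp_aligner import dp_optimal
from pdthread.global_energy import PairPotentialTable
from pdthread.local_search import (SearchParams, ValidationError,
                                   combined_score_fn, fast_combined_score_fn,
                                   local_search, local_search_with_trace,
                                   neighborhood, neighborhood_oracle,
                                   score_lower_bound, thread)
from pdthread.local_scoring import LocalWeights
from pdthread.synthetic_fixtures import make_rescue_pair
from conftest import random_alignment, random_instance


class TestNeighborhood:
    def test_k1_small_example_covers_space(self):
        a = AlignmentMapping(2, 1, (0, 0))
        got = {x.map for x in neighborhood(a, 1)}
        assert got == {x.map for x in enumerate_all_alignments(2, 1)}

    def test_equals_oracle_on_grid(self):
        rng = np.random.default_rng(0)
        for m in range(1, 5):
            for n in range(1, 4):
                bases = [random_alignment(m, n, rng) for _ in range(4)]
                bases.append(AlignmentMapping(m, n, (0,) * m))
                for a in bases:
                    for k in range(1, 4):
                        got = {x.map for x in neighborhood(a, k)}
                        assert got == neighborhood_oracle(a, k, m, n)

    def test_nesting_claim(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = random_alignment(4, 3, rng)
            sets = [{x.map for x in neighborhood(a, k)} for k in (1, 2, 3)]
            assert sets[0] <= sets[1] <= sets[2]

    def test_full_space_at_k_n_plus_1(self):
        rng = np.random.default_rng(2)
        for (m, n) in [(3, 2), (4, 3), (2, 4)]:
            a = random_alignment(m, n, rng)
            got = {x.map for x in neighborhood(a, n + 1)}
            assert got == {x.map for x in enumerate_all_alignments(m, n)}

    def test_k1_size_polynomially_bounded(self):
        """|N(A, 1)| <= 1 + (n + 1) m (m + 1) / 2: one rerouted value times
        one contiguous interval."""
        rng = np.random.default_rng(3)
        n = 4
        for m in range(2, 9):
            a = random_alignment(m, n, rng)
            size = len(neighborhood(a, 1))
            assert size <= 1 + (n + 1) * m * (m + 1) // 2

    def test_contains_self_and_k_guard(self):
        a = AlignmentMapping(3, 2, (0, 1, 2))
        assert a in neighborhood(a, 1)
        with pytest.raises(ValidationError):
            neighborhood(a, 0)
        with pytest.raises(ValidationError):
            neighborhood_oracle(a, 0, 3, 2)


def _scored_instance(seed, m=4, n=4, omega_l=0.3):
    rng = np.random.default_rng(seed)
    template, query, weights = random_instance(m, n, rng)
    from pdthread.global_energy import estimate_potential
    table = estimate_potential([template], typer="cb")
    fn = fast_combined_score_fn(template, query, weights, table, omega_l)
    shift = 1.0 - score_lower_bound(template, query, weights, table,
                                    omega_l)
    return template, query, fn, shift


class TestLocalSearch:
    def test_fixed_point_returns_start(self):
        template, query, fn, shift = _scored_instance(5)
        # the exhaustive optimum is a fixed point of any neighbourhood scan
        best = min((a for a in enumerate_all_alignments(template.m, query.n)
                    if math.isfinite(fn(a))), key=lambda a: (fn(a), a.map))
        params = SearchParams(alpha=0.0, k=1, score_shift=shift)
        out, trace = local_search_with_trace(best, fn, params)
        assert out == best and len(trace) == 1

    def test_global_optimum_at_alpha0_full_k(self):
        for seed in range(6):
            template, query, fn, shift = _scored_instance(seed)
            n = query.n
            ref = min((fn(a) for a in
                       enumerate_all_alignments(template.m, n)
                       if math.isfinite(fn(a))))
            rng = np.random.default_rng(seed + 100)
            a0 = random_alignment(template.m, n, rng)
            if not math.isfinite(fn(a0)):
                a0 = AlignmentMapping(template.m, n,
                                      tuple(range(1, template.m + 1)))
            params = SearchParams(alpha=0.0, k=n + 1, score_shift=shift)
            out = local_search(a0, fn, params)
            assert fn(out) == pytest.approx(ref, abs=1e-9)

    def test_huge_alpha_accepts_nothing(self):
        template, query, fn, shift = _scored_instance(7)
        a0 = AlignmentMapping(template.m, query.n,
                              tuple(range(1, template.m + 1)))
        params = SearchParams(alpha=1e6, k=1, score_shift=shift)
        assert local_search(a0, fn, params) == a0

    def test_trajectory_strictly_decreasing_with_log_bound(self):
        for seed in range(5):
            template, query, fn, shift = _scored_instance(seed, m=5, n=5)
            a0 = AlignmentMapping(template.m, query.n,
                                  (0,) * (template.m - 1) + (query.n,))
            alpha = 0.01
            params = SearchParams(alpha=alpha, k=1, score_shift=shift)
            out, trace = local_search_with_trace(a0, fn, params)
            shifted = [s + shift for s in trace]
            assert all(v > 0 for v in shifted)
            for prev, nxt in zip(shifted, shifted[1:]):
                assert (1 + alpha) * nxt < prev
            steps = len(trace) - 1
            if steps:
                bound = math.log(shifted[0] / shifted[-1]) \
                    / math.log(1 + alpha) + 1
                assert steps <= bound

    def test_nonfinite_start_rejected(self):
        template, query, fn, _ = _scored_instance(9)
        empty = AlignmentMapping(template.m, query.n, (0,) * template.m)
        with pytest.raises(ValidationError):
            local_search(empty, fn, SearchParams())


class TestThreadDriver:
    def test_gate_always_fires_with_infinite_theta(self):
        q, t, ref, table, w, om = make_rescue_pair()
        res = thread(q, t, theta=math.inf, omega_l=om, table=table,
                     weights=w, seed=1)
        assert res.provenance == "easy"
        a_l, _, _ = dp_optimal(t, q, w)
        assert res.alignment == a_l

    def test_zero_table_reduces_to_local_item(self):
        q, t, ref, _, w, om = make_rescue_pair()
        zero = PairPotentialTable.zeros(typer="cb")
        res = thread(q, t, theta=-math.inf, omega_l=om, table=zero,
                     weights=w, seed=1)
        assert res.provenance == "searched"
        _, _, l_norm = dp_optimal(t, q, w)
        assert res.breakdown.combined <= om * l_norm + 1e-12
        assert res.breakdown.global_total == 0.0

    def test_rescue_reference_is_combined_optimum(self):
        q, t, ref, table, w, om = make_rescue_pair()
        fn = combined_score_fn(t, q, w, table, om)
        best = min((a for a in enumerate_all_alignments(t.m, q.n)
                    if math.isfinite(fn(a))), key=lambda a: (fn(a), a.map))
        assert best == ref

    def test_rescue_thread_beats_dp(self):
        q, t, ref, table, w, om = make_rescue_pair()
        a_l, _, _ = dp_optimal(t, q, w)
        res = thread(q, t, theta=-87.0, omega_l=om, table=table,
                     weights=w, seed=3)
        assert res.provenance == "searched"
        acc_dp = alignment_accuracy(a_l, ref)
        acc_thread = alignment_accuracy(res.alignment, ref)
        assert acc_dp == 0.0 and acc_thread == 1.0

    def test_fast_and_slow_scorers_agree(self):
        q, t, ref, table, w, om = make_rescue_pair()
        slow = combined_score_fn(t, q, w, table, om)
        fast = fast_combined_score_fn(t, q, w, table, om)
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = random_alignment(t.m, q.n, rng)
            s, f = slow(a), fast(a)
            assert (math.isinf(s) and math.isinf(f)) or \
                s == pytest.approx(f, abs=1e-9)

    def test_searched_result_not_worse_than_dp_start(self):
        q, t, ref, table, w, om = make_rescue_pair()
        res = thread(q, t, theta=-math.inf, omega_l=om, table=table,
                     weights=w, seed=5)
        fn = combined_score_fn(t, q, w, table, om)
        assert fn(res.alignment) <= fn(res.dp_alignment) + 1e-12
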