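import numpy as np
import pytest

from pdthread.alignment_core import AlignmentMapping, from_match_states
from pdthread.io_models import AA_ALPHABET, QueryProfile
from pdthread.local_scoring import LocalWeights
from pdthread.synthetic_fixtures import (make_ideal_structure,
                                         make_threading_pair)


def random_alignment(m: int, n: int, rng: np.random.Generator
                     ) -> AlignmentMapping:
    """Uniformly structured random valid alignment via a random
    match-state list (possibly empty)."""
    k = int(rng.integers(0, min(m, n) + 1))
    ts = sorted(rng.choice(np.arange(1, m + 1), size=k, replace=False))
    ss = sorted(rng.choice(np.arange(1, n + 1), size=k, replace=False))
    return from_match_states(list(zip(ts, ss)), m, n)


def random_instance(m: int, n: int, rng: np.random.Generator):
    """Random small threading instance (template, query, weights) for
    exhaustive-oracle comparisons."""
    t = make_ideal_structure(max(m, 4), "mixed",
                             seed=int(rng.integers(2 ** 31 - 1)))
    template = t.subset(range(1, m + 1))
    seq = "".join(rng.choice(list(AA_ALPHABET), size=n))
    query = QueryProfile(seq, rng.normal(scale=2.0, size=(n, 20)),
                         "".join(rng.choice(list("HEC"), size=n)),
                         "".join(rng.choice(list("BE"), size=n)))
    weights = LocalWeights(w_m=1.0,
                           w_ss=float(rng.uniform(0, 1)),
                           w_sa=float(rng.uniform(0, 1)),
                           w_cle=0.0,
                           w_go=float(rng.uniform(0, 3)),
                           w_ge=float(rng.uniform(0, 1)))
    return template, query, weights


def brute_force_minimum(template, query, weights, free_query_ends=True,
                        free_template_ends=False):
    """Exhaustive raw-local-score minimum over every valid alignment."""
    from pdthread.alignment_core import enumerate_all_alignments, match_states
    from pdthread.dp_aligner import raw_score_of_matches
    from pdthread.local_scoring import position_cost_matrix
    cost = position_cost_matrix(template, query, weights)
    best, best_a = np.inf, None
    for a in enumerate_all_alignments(template.m, query.n):
        s = raw_score_of_matches(match_states(a), cost, weights,
                                 template.m, query.n, free_query_ends,
                                 free_template_ends)
        if s < best:
            best, best_a = s, a
    return best, best_a


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_structure(12, "helix", seed=11)


@pytest.fixture(scope="session")
def mixed24():
    return make_ideal_structure(24, "mixed", seed=7)


@pytest.fixture(scope="session")
def threading_pair():
    return make_threading_pair(seed=2)


@pytest.fixture(scope="session")
def default_weights():
    return LocalWeights()
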