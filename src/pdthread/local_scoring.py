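"""The local score item L(A): a weighted sum of mutation, secondary
structure, solvent accessibility and structural-alphabet compatibility over
match states plus an affine gap penalty, normalized by match-state size.

Sign convention: the threading problem is a minimization, so similarity-like
quantities (profile log-odds, structural-alphabet substitution scores) enter
negated; mismatch indicators and gap counts enter positively.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Callable, Optional, Tuple

import numpy as np

from .alignment_core import AlignmentMapping, count_gaps, match_states
from .io_models import AA_INDEX, QueryProfile, Template

INFEASIBLE = math.inf  # sentinel for alignments with no match states


@dataclass(frozen=True)
class LocalWeights:
    """Weights of the local-score components. The shipped defaults are
    placeholders meant to be overridden from a config file; gap weights
    must be non-negative."""

    w_m: float = 1.0
    w_ss: float = 0.5
    w_cle: float = 0.5
    w_sa: float = 0.2
    w_go: float = 3.0
    w_ge: float = 0.5

    def __post_init__(self):
        vals = asdict(self)
        if not all(math.isfinite(v) for v in vals.values()):
            raise ValueError("weights must be finite")
        if self.w_go < 0 or self.w_ge < 0:
            raise ValueError("gap weights must be non-negative")

    @classmethod
    def from_file(cls, path) -> "LocalWeights":
        """Read weights from a JSON or TOML key-value file."""
        text = open(path, "rb").read()
        if str(path).endswith(".toml"):
            import tomllib
            data = tomllib.loads(text.decode())
        else:
            data = json.loads(text.decode())
        return cls(**{k: float(v) for k, v in data.items()})

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class ScoreBreakdown:
    """Per-component report for one scored alignment."""

    s_m: float = 0.0
    s_ss: float = 0.0
    s_cle: float = 0.0
    s_sa: float = 0.0
    go: int = 0
    ge: int = 0
    match_size: int = 0
    local_total: float = INFEASIBLE    # normalized L(A)
    global_total: float = INFEASIBLE   # normalized G(A)
    combined: float = INFEASIBLE       # omega_L * L + G

    def to_tsv(self) -> str:
        d = asdict(self)
        keys = list(d)
        return ("\t".join(keys) + "\n"
                + "\t".join(str(d[k]) for k in keys) + "\n")


def identity_cle_matrix(a: str, b: str) -> float:
    """Identity substitution over structural-alphabet letters; undefined
    letters ('-') score 0."""
    if a == "-" or b == "-":
        return 0.0
    return 1.0 if a == b else 0.0


def position_local_score(
    t: int, s: int, template: Template, query: QueryProfile,
    cle_matrix: Callable[[str, str], float] = identity_cle_matrix,
) -> Tuple[float, float, float, float]:
    """(mutation, ss, sa, cle) components for matching template position t
    with query position s (both 1-based).

    mutation = -profile[s][aa(template, t)]; ss and sa are 0/1 mismatch
    indicators; cle = -substitution(template letter, predicted query letter),
    0 when the query carries no structural-alphabet prediction.
    """
    if not 1 <= t <= template.m:
        raise IndexError(f"template position {t} outside 1..{template.m}")
    if not 1 <= s <= query.n:
        raise IndexError(f"query position {s} outside 1..{query.n}")
    aa = template.residues[t - 1].one_letter
    mutation = -float(query.profile[s - 1, AA_INDEX[aa]]) if aa in AA_INDEX \
        else 0.0
    ss = 0.0 if template.ss[t - 1] == query.predicted_ss[s - 1] else 1.0
    sa = 0.0 if template.burial[t - 1] == query.predicted_burial[s - 1] \
        else 1.0
    if query.predicted_cle is None:
        cle = 0.0
    else:
        cle = -cle_matrix(template.cle[t - 1], query.predicted_cle[s - 1])
    return mutation, ss, sa, cle


def position_cost_matrix(
    template: Template, query: QueryProfile, weights: LocalWeights,
    cle_matrix: Callable[[str, str], float] = identity_cle_matrix,
) -> np.ndarray:
    """(m, n) matrix of weighted per-position match costs."""
    m, n = template.m, query.n
    # vectorized mutation term
    aa_idx = np.array([AA_INDEX.get(r.one_letter, -1)
                       for r in template.residues])
    mut = np.zeros((m, n))
    ok = aa_idx >= 0
    mut[ok] = -query.profile[:, aa_idx[ok]].T
    ss_t = np.frombuffer(template.ss.encode(), dtype="S1")
    ss_q = np.frombuffer(query.predicted_ss.encode(), dtype="S1")
    ss = (ss_t[:, None] != ss_q[None, :]).astype(float)
    sa_t = np.frombuffer(template.burial.encode(), dtype="S1")
    sa_q = np.frombuffer(query.predicted_burial.encode(), dtype="S1")
    sa = (sa_t[:, None] != sa_q[None, :]).astype(float)
    cost = weights.w_m * mut + weights.w_ss * ss + weights.w_sa * sa
    if query.predicted_cle is not None:
        cle = np.empty((m, n))
        for i in range(m):
            for j in range(n):
                cle[i, j] = -cle_matrix(template.cle[i],
                                        query.predicted_cle[j])
        cost += weights.w_cle * cle
    return cost


def raw_local_score(
    a: AlignmentMapping, template: Template, query: QueryProfile,
    weights: LocalWeights,
    cle_matrix: Callable[[str, str], float] = identity_cle_matrix,
    free_query_ends: bool = True, free_template_ends: bool = False,
) -> float:
    """Unnormalized local score: sum of weighted positional components over
    match states plus w_go*GO + w_ge*GE."""
    total = 0.0
    for t, s in match_states(a):
        mu, ss, sa, cle = position_local_score(t, s, template, query,
                                               cle_matrix)
        total += (weights.w_m * mu + weights.w_ss * ss
                  + weights.w_sa * sa + weights.w_cle * cle)
    go, ge = count_gaps(a, free_query_ends, free_template_ends)
    return total + weights.w_go * go + weights.w_ge * ge


def local_score(
    a: AlignmentMapping, template: Template, query: QueryProfile,
    weights: LocalWeights,
    cle_matrix: Callable[[str, str], float] = identity_cle_matrix,
    free_query_ends: bool = True, free_template_ends: bool = False,
) -> float:
    """Normalized local score L(A) = raw / match-state size; +inf for
    alignments with no match states (never scored in practice)."""
    size = len(match_states(a))
    if size == 0:
        return INFEASIBLE
    return raw_local_score(a, template, query, weights, cle_matrix,
                           free_query_ends, free_template_ends) / size


def score_breakdown(
    a: AlignmentMapping, template: Template, query: QueryProfile,
    weights: LocalWeights, omega_l: Optional[float] = None,
    global_total: Optional[float] = None,
    cle_matrix: Callable[[str, str], float] = identity_cle_matrix,
    free_query_ends: bool = True, free_template_ends: bool = False,
) -> ScoreBreakdown:
    pairs = match_states(a)
    bd = ScoreBreakdown(match_size=len(pairs))
    for t, s in pairs:
        mu, ss, sa, cle = position_local_score(t, s, template, query,
                                               cle_matrix)
        bd.s_m += mu
        bd.s_ss += ss
        bd.s_sa += sa
        bd.s_cle += cle
    bd.go, bd.ge = count_gaps(a, free_query_ends, free_template_ends)
    if pairs:
        raw = (weights.w_m * bd.s_m + weights.w_ss * bd.s_ss
               + weights.w_sa * bd.s_sa + weights.w_cle * bd.s_cle
               + weights.w_go * bd.go + weights.w_ge * bd.ge)
        bd.local_total = raw / bd.match_size
    if global_total is not None:
        bd.global_total = global_total
        if omega_l is not None and pairs:
            bd.combined = omega_l * bd.local_total + global_total
    return bd
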