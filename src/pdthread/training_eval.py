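"""Training and evaluation utilities: the slope-maximization trainer for
the local-item weight omega_L, the easy-pair threshold theta, a TM-score
style structural quality measure, and the partial-structure discrimination
experiment.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._geometry import apply_transform, kabsch
from .alignment_core import AlignmentMapping, match_states
from .global_energy import (DEFAULT_MIN_SEPARATION, PairPotentialTable,
                            decoy_energy)
from .io_models import Template
from .partial_decoy import excise_random

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass
class TrainingPair:
    """Normalized scores of one positive alignment and its negatives for
    one query-template pair."""

    pair_id: str
    l_pos: float
    g_pos: float
    negatives: List[Tuple[float, float]]   # (L_neg, G_neg)

    def __post_init__(self):
        if not self.negatives:
            raise ValidationError("a training pair needs >= 1 negative")

    def points(self) -> List[Tuple[float, float]]:
        """(x, y) = (L_pos - L_neg, G_neg - G_pos) per negative; the
        positive is separated by omega exactly when omega * x < y."""
        return [(self.l_pos - ln, gn - self.g_pos)
                for ln, gn in self.negatives]


def train_omega(points: Sequence[Tuple[float, float]]
                ) -> Tuple[float, int]:
    """The strictly positive slope omega maximizing the number of points
    with omega * x < y (a positive-slope line with the most points above
    it). The count is piecewise constant in omega with breakpoints at the
    positive ratios y / x, so scanning one candidate inside each open
    interval is exact. Ties go to the smallest maximizing candidate."""
    if not points:
        raise ValidationError("no training points")
    breaks = sorted({y / x for x, y in points if x != 0 and y / x > 0})
    if not breaks:
        candidates = [1.0]
    else:
        candidates = [breaks[0] / 2.0]
        candidates += [0.5 * (a + b) for a, b in zip(breaks, breaks[1:])]
        candidates.append(breaks[-1] * 2.0)

    def count(w: float) -> int:
        return sum(1 for x, y in points if w * x < y)

    best_w, best_h = candidates[0], count(candidates[0])
    for w in candidates[1:]:
        h = count(w)
        if h > best_h or (h == best_h and w < best_w):
            best_w, best_h = w, h
    if best_h == 0:
        logger.warning("no positive slope separates any training point")
        return min(candidates), 0
    return best_w, best_h


def _match_set_jaccard(a: AlignmentMapping, b: AlignmentMapping) -> float:
    sa, sb = set(match_states(a)), set(match_states(b))
    union = sa | sb
    return len(sa & sb) / len(union) if union else 1.0


def select_negatives(candidates: Sequence[Tuple[AlignmentMapping, float]],
                     reference_quality: float, count: int = 10,
                     similarity_threshold: float = 0.8, seed: int = 0,
                     quality_gap: float = 0.2
                     ) -> List[Tuple[AlignmentMapping, float]]:
    """Negative alignments for weight training: greedy clustering on
    match-state overlap keeps one representative per cluster, eligibility
    requires reference_quality - quality > quality_gap, and `count` of the
    eligible representatives are sampled uniformly under `seed`."""
    reps: List[Tuple[AlignmentMapping, float]] = []
    for a, q in candidates:
        if all(_match_set_jaccard(a, r) < similarity_threshold
               for r, _ in reps):
            reps.append((a, q))
    eligible = [(a, q) for a, q in reps if reference_quality - q > quality_gap]
    if not eligible:
        logger.warning("no eligible negative alignments")
        return []
    if len(eligible) <= count:
        return eligible
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(eligible), size=count, replace=False))
    return [eligible[i] for i in idx]


def select_theta(records: Sequence[Tuple[float, float]],
                 gap_limit: float = 0.1) -> float:
    """The easy-pair threshold: with records (normalized local score of
    A_L, quality gap TM(A_R) - TM(A_L)) sorted by score, theta is the
    largest score whose running mean of quality gaps stays below
    `gap_limit`; -inf when even the first record violates it."""
    if len(records) < 2:
        raise ValidationError("need >= 2 records to select theta")
    ordered = sorted(records, key=lambda r: r[0])
    theta = -math.inf
    total = 0.0
    for i, (score, gap) in enumerate(ordered, start=1):
        total += gap
        if total / i < gap_limit:
            theta = score
        else:
            break
    return theta


# --------------------------------------------------------------------------
# TM-score style quality

def _tm_d0(l_target: int) -> float:
    if l_target > 15:
        return max(1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def tm_quality(a: AlignmentMapping, query_structure: Template,
               template: Template) -> float:
    """TM-score style structural quality of an alignment, in (0, 1].

    Matched C-alpha pairs are superposed by the standard least-squares
    rotation; the iteration seeds rigid fits on sliding fragments of
    decreasing length and refines each on the close pairs until the
    selected set is stable, keeping the best score

        TM = max (1 / L_target) * sum_i 1 / (1 + (d_i / d0)^2)

    with L_target the query length and
    d0 = max(1.24 * (L_target - 15)^(1/3) - 1.8, 0.5).
    """
    pairs = match_states(a)
    if len(pairs) < 3:
        raise ValidationError("need >= 3 match states for superposition")
    tmpl = np.array([template.residues[t - 1].atoms["CA"] for t, _ in pairs])
    qry = np.array([query_structure.residues[s - 1].atoms["CA"]
                    for _, s in pairs])
    l_target = query_structure.m
    d0 = _tm_d0(l_target)
    n_ali = len(pairs)

    def score_from(sel: np.ndarray) -> Tuple[float, np.ndarray]:
        r, t = kabsch(tmpl[sel], qry[sel])
        moved = apply_transform(tmpl, r, t)
        d = np.linalg.norm(moved - qry, axis=1)
        return float((1.0 / (1.0 + (d / d0) ** 2)).sum() / l_target), d

    best = 0.0
    frag = n_ali
    frag_lengths = []
    while frag >= 3:
        frag_lengths.append(frag)
        frag //= 2
    for lf in frag_lengths:
        step = max(1, lf // 2)
        for start in range(0, n_ali - lf + 1, step):
            sel = np.zeros(n_ali, dtype=bool)
            sel[start:start + lf] = True
            prev = None
            for _ in range(20):
                score, d = score_from(sel)
                best = max(best, score)
                d_cut = d0
                new = d < d_cut
                while new.sum() < 3:
                    d_cut += 0.5
                    new = d < d_cut
                if prev is not None and np.array_equal(new, prev):
                    break
                prev, sel = new, new
    return best


# --------------------------------------------------------------------------
# partial-structure discrimination

def partial_discrimination(native: Template, decoys: Sequence[Template],
                           table: PairPotentialTable,
                           keep_fractions: Sequence[float],
                           trials: int = 10, seed: int = 0,
                           min_separation: int = DEFAULT_MIN_SEPARATION
                           ) -> Dict[float, float]:
    """Fraction of trials in which the partial native structure has
    strictly the lowest energy among the identically excised decoys,
    per keep fraction. The same residue-index set is excised from the
    native and from every decoy in each trial."""
    if not decoys:
        raise ValidationError("no decoys supplied")
    for d in decoys:
        if d.m != native.m:
            raise ValidationError("decoys must match the native length")
    if trials < 1:
        raise ValidationError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    out: Dict[float, float] = {}
    for frac in keep_fractions:
        wins = 0
        for _ in range(trials):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            part_native = excise_random(native, frac, sub_seed)
            e_nat = decoy_energy(part_native, table, min_separation)
            e_dec = [decoy_energy(excise_random(d, frac, sub_seed),
                                  table, min_separation) for d in decoys]
            if e_nat < min(e_dec):
                wins += 1
        out[frac] = wins / trials
    return out


def write_discrimination_table(results: Dict[float, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("keep_fraction\taccuracy\n")
        for frac in sorted(results):
            fh.write(f"{frac:g}\t{results[frac]:g}\n")
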