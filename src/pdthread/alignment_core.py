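"""Alignments as non-decreasing mappings from template positions to query
positions.

A valid alignment maps each template position t in 1..m to a query position
A(t) in 0..n, non-decreasingly; the sentinel value 0 encodes a left-end
template gap. For each query position s > 0 in the image, the smallest t
with A(t) = s is the match; the remaining template positions mapping to s
are template-side gaps. A valid mapping is therefore uniquely determined by
its match-state list, which makes the gapped-string form canonical and
gives |F| = binomial(m + n, m) valid alignments in total.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterator, List, Optional, Tuple

ENUMERATION_GUARD = 10 ** 6


class ValidationError(ValueError):
    pass


class AlignmentParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentMapping:
    """Non-decreasing map from template positions 1..m to {0, 1, ..., n}."""

    m: int
    n: int
    map: Tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "map", tuple(int(v) for v in self.map))
        if len(self.map) != self.m:
            raise ValidationError(
                f"map length {len(self.map)} != m = {self.m}")

    def __call__(self, t: int) -> int:
        return self.map[t - 1]


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    position: Optional[int] = None   # first offending template position
    message: str = ""


def validate(a: AlignmentMapping) -> ValidationReport:
    """Check monotonicity and range; reports the first violation."""
    prev = 0
    for t, v in enumerate(a.map, start=1):
        if not 0 <= v <= a.n:
            return ValidationReport(False, t,
                                    f"A({t}) = {v} outside [0, {a.n}]")
        if v < prev:
            return ValidationReport(
                False, t, f"A({t}) = {v} < A({t - 1}) = {prev}")
        prev = v
    return ValidationReport(True)


def require_valid(a: AlignmentMapping) -> None:
    rep = validate(a)
    if not rep.ok:
        raise ValidationError(rep.message)


def match_states(a: AlignmentMapping) -> List[Tuple[int, int]]:
    """Matched (t, s) pairs: for each s > 0 in the image, the smallest t
    with A(t) = s. Strictly increasing in both coordinates."""
    require_valid(a)
    pairs = []
    prev = 0
    for t, v in enumerate(a.map, start=1):
        if v > prev:
            pairs.append((t, v))
        prev = v
    return pairs


def match_state_size(a: AlignmentMapping) -> int:
    return len(match_states(a))


def from_match_states(pairs, m: int, n: int) -> AlignmentMapping:
    """The unique valid mapping with the given match-state list."""
    mp = [0] * m
    last_s = 0
    pairs = sorted(pairs)
    k = 0
    for t in range(1, m + 1):
        if k < len(pairs) and pairs[k][0] == t:
            last_s = pairs[k][1]
            k += 1
        mp[t - 1] = last_s
    return AlignmentMapping(m, n, tuple(mp))


def to_gapped_strings(a: AlignmentMapping, template_seq: str,
                      query_seq: str) -> Tuple[str, str]:
    """Canonical gapped-string form: within each inter-match block,
    template-side gap columns precede query-side insertion columns."""
    require_valid(a)
    if len(template_seq) != a.m or len(query_seq) != a.n:
        raise ValidationError("sequence lengths do not match m, n")
    pairs = match_states(a)
    trow, qrow = [], []
    pt, ps = 0, 0  # last consumed template / query positions
    for (t, s) in pairs + [(a.m + 1, a.n + 1)]:
        for td in range(pt + 1, t):          # deletions first
            trow.append(template_seq[td - 1])
            qrow.append("-")
        for si in range(ps + 1, s):          # then insertions
            trow.append("-")
            qrow.append(query_seq[si - 1])
        if t <= a.m:
            trow.append(template_seq[t - 1])
            qrow.append(query_seq[s - 1])
        pt, ps = t, s
    return "".join(trow), "".join(qrow)


def from_gapped_strings(trow: str, qrow: str) -> AlignmentMapping:
    """Inverse of :func:`to_gapped_strings`."""
    if len(trow) != len(qrow):
        raise AlignmentParseError("gapped rows have unequal length")
    m = sum(c != "-" for c in trow)
    n = sum(c != "-" for c in qrow)
    mp = []
    s = 0
    last_s = 0
    for col, (tc, qc) in enumerate(zip(trow, qrow), start=1):
        if tc == "-" and qc == "-":
            raise AlignmentParseError(f"column {col}: gap in both rows")
        if tc != "-" and qc != "-":
            s += 1
            last_s = s
            mp.append(s)
        elif tc != "-":
            mp.append(last_s)
        else:
            s += 1
    return AlignmentMapping(m, n, tuple(mp))


def _gap_blocks(a: AlignmentMapping):
    """Per-block (deletions, insertions) counts: block 0 precedes the first
    match, block i follows match i."""
    pairs = match_states(a)
    blocks = []
    pt, ps = 0, 0
    for (t, s) in pairs + [(a.m + 1, a.n + 1)]:
        blocks.append((t - pt - 1, s - ps - 1))
        pt, ps = t, s
    return blocks


def count_gaps(a: AlignmentMapping, free_query_ends: bool = True,
               free_template_ends: bool = False) -> Tuple[int, int]:
    """(GO, GE): number of maximal gap runs and total gapped columns in the
    canonical gapped-string form. With `free_query_ends` (the threading
    default) terminal unaligned query runs are not counted; analogously for
    `free_template_ends` on the template side."""
    blocks = _gap_blocks(a)
    go = ge = 0
    last = len(blocks) - 1
    for i, (dels, ins) in enumerate(blocks):
        terminal = i == 0 or i == last
        if dels and not (terminal and free_template_ends):
            go += 1
            ge += dels
        if ins and not (terminal and free_query_ends):
            go += 1
            ge += ins
    return go, ge


def alignment_accuracy(test: AlignmentMapping, reference: AlignmentMapping,
                       tolerance: int = 0) -> float:
    """Fraction of reference match states (t, s) for which the test
    alignment matches t to some s' with |s' - s| <= tolerance."""
    if (test.m, test.n) != (reference.m, reference.n):
        raise ValidationError("alignments are over different instances")
    ref = match_states(reference)
    if not ref:
        raise ValidationError("reference alignment has no match states")
    tst = dict(match_states(test))
    correct = sum(1 for (t, s) in ref
                  if t in tst and abs(tst[t] - s) <= tolerance)
    return correct / len(ref)


def enumerate_all_alignments(m: int, n: int) -> Iterator[AlignmentMapping]:
    """All valid alignments (test oracle); exactly binomial(m + n, m) of
    them. Refuses instances with more than 10^6 alignments."""
    total = comb(m + n, m)
    if total > ENUMERATION_GUARD:
        raise ValidationError(
            f"{total} alignments exceeds enumeration guard")
    for tup in itertools.combinations_with_replacement(range(n + 1), m):
        yield AlignmentMapping(m, n, tup)


def write_gapped_fasta(a: AlignmentMapping, template_seq: str,
                       query_seq: str, path, template_name="template",
                       query_name="query") -> None:
    trow, qrow = to_gapped_strings(a, template_seq, query_seq)
    with open(path, "w") as fh:
        fh.write(f">{template_name}\n{trow}\n>{query_name}\n{qrow}\n")


def write_match_states(a: AlignmentMapping, path) -> None:
    with open(path, "w") as fh:
        for t, s in match_states(a):
            fh.write(f"{t}\t{s}\n")
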