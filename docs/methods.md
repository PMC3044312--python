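# Methods

## The model

`pdthread` scores a query-template alignment **A** with

    score(A) = omega_L * L(A) + G(A)

and minimizes it over the space **F** of valid alignments. Both items are
normalized by the match-state size, because raw local and global scores
grow linearly with the number of matched residues and would otherwise make
scores of differently sized alignments incomparable.

**Alignments as monotone mappings.** A valid alignment is a non-decreasing
map A from template positions 1..m to query positions {0, 1, ..., n}; the
sentinel value 0 encodes a left-end template gap. For each query position
s > 0 in the image, the smallest template position mapping to s is the
*match state*; the remaining positions mapping to s are template-side
gaps. Two useful consequences, both exploited throughout the code and
verified by the test suite:

* a valid mapping is uniquely determined by its match-state list (gap
  residues are forced onto the query index of the preceding match), which
  makes the gapped-string form canonical, and
* |**F**| = binomial(m + n, m), which the enumeration oracle uses as an
  exact cardinality check.

**Local item.** L(A) is the weighted sum, over match states, of a
mutation score (negated profile log-odds of the template residue at the
query position), 0/1 secondary-structure and burial-class mismatch
indicators, and a structural-alphabet substitution term, plus an affine
gap penalty `w_go * GO + w_ge * GE`, all divided by the match-state size.
The functional forms of the four positional components are deliberately
the simplest ones consistent with their inputs and are pluggable
callbacks; the shipped weights (`w_m=1, w_ss=0.5, w_sa=0.2, w_cle=0.5,
w_go=3, w_ge=0.5`) are placeholders meant to be overridden from a JSON or
TOML config, since meaningful values must be fit to a reference alignment
benchmark.

*Gap-count convention.* `GO` counts maximal gap runs over both rows of the
canonical gapped form and `GE` counts every gapped column, so an opened
gap of length L contributes GO=1, GE=L: an affine model equivalent to the
usual open+extend after reparameterization. Within each inter-match block
the canonical form emits template-side gap columns before query-side
insertion columns; the dynamic program enforces the same order, which is
what makes the DP objective identical to the scored gapped form. Terminal
gap handling is configurable: by default unaligned query tails are free
(the threading convention — the query may be longer than the modeled
region) while unaligned template residues are always penalized. Both
flags are explicit parameters everywhere gaps are counted.

**Global item.** G(A) is a distance-dependent pairwise statistical
potential evaluated on the *partial decoy*: one residue per match state,
typed by the query residue but sitting verbatim on the template
coordinates of the paired residue. Copying coordinates (rather than
building a full-length model per alignment) is what makes the energy
cheap enough to evaluate thousands of times inside a search; typing by
the query is what makes it depend on the alignment at all. Query glycines
drop the Cbeta; when a non-glycine query residue lands on a glycine
template residue an ideal Cbeta (1.521 Å, tetrahedral) is reconstructed
from the backbone so the atom set stays uniform. Backbone O atoms are
kept (a harmless superset of the backbone).

The potential follows the DFIRE construction with a finite-ideal-gas
reference state,

    E(a,b,r_k) = -eta * ln[ N(a,b,r_k) /
                 ((r_k/r_cut)^alpha * (dr_k/dr_cut) * N(a,b,r_cut)) ]

with additive pseudocount 0.5 and a zero row for unobserved type pairs.
Defaults: r_cut = 15 Å, 30 bins of 0.5 Å, alpha = 1.61, eta = 0.01,
minimum sequence separation 2, atom typing either one center per residue
(Cbeta, Calpha for glycine; 20 types) or residue x atom-name (100 types).
The published potentials this stands in for include an orientation
(dipole) term that is out of scope here; the energy callback is pluggable
so an externally fitted table can be swapped in unchanged.

**Contact-preference baseline.** For comparison, the distance-independent
score S_p sums profile-weighted amino-acid pair preferences
P_i^T C P_j over template contacts (Cbeta distance <= 8 Å, sequence
separation >= 4 — a conventional choice, the contact definition is not
prescribed by the framework) whose both ends are match states, negated
and normalized. Profile rows are converted to probability vectors by
softmax unless explicit probabilities are passed.

## Optimization

**Seeding.** A three-state affine-gap dynamic program minimizes the raw
(unnormalized) local score exactly; normalization by match-state size
makes the objective non-decomposable, so the optimum A_L is defined on
the raw score and its normalized value is reported for the easy-pair
gate. Suboptimal seeds are drawn by Boltzmann-weighted stochastic
traceback over a soft-min version of the same tables at fixed temperature
(default 1.0), seeded and deduplicated; the exact optimum is always the
first candidate. This is one concrete reading of "the best alignments
from the DP table"; it was chosen because it is reproducible and yields
diverse suboptimal seeds with a guaranteed inclusion of the optimum.

**k-neighborhood.** N(A, k) contains every valid A' whose differing
positions take at most k new query values. The enumerator uses an exact
interval construction for k = 1 (for each candidate value, the rerouted
positions form a contiguous interval) and a per-value-set monotone DFS
for k >= 2; both are checked for set equality against a brute-force
filter of the full space implementing the definition as a predicate.
Nesting N(A,k) ⊆ N(A,k+1), full coverage N(A, n+1) = F, and the
polynomial bound |N(A,1)| <= 1 + (n+1) m (m+1)/2 are asserted in tests.

**Local search.** From each seed, repeatedly move to the neighborhood
argmin and accept only when `(1 + alpha) * score(A_next) < score(A_cur)`.
The multiplicative test presumes positive scores while realistic scores
are negative, so it is applied to shifted scores `score + shift` with
`shift = 1 - lower_bound` and a cheap per-instance lower bound (sum of
negative per-position cost minima for the local part, table minimum times
the maximal pair count for the energy). alpha = 0 is unaffected by the
shift and gives an exact local optimum; with alpha = 0 and k = n + 1 a
single accepted chain reaches the exact global optimum, which the tests
verify against exhaustive enumeration. Strict decrease on a finite space
guarantees termination; an iteration cap (default 1000) is belt and
braces, and the accepted-step count obeys the logarithmic bound
`log_{1+alpha}(shifted_initial / shifted_final) + 1`. Ties in the argmin
go to the lexicographically smallest mapping for full determinism.

**Driver.** Threading proceeds as: (1) compute A_L and up to 100 seeds by
DP; (2) if normalized L(A_L) < theta, return A_L ("easy" — the local item
alone is trusted when the pair is clearly homologous, and adding the
energy term mainly injects noise there); (3) otherwise run the local
search from every seed under the combined score and return the best
result, ties again broken lexicographically. The shipped defaults
theta = -87 and omega_L = 0.0047 are calibrated for a particular
benchmark-trained weight scale; they are only meaningful with comparably
scaled local scores, which is why the CLI warns when custom weights are
supplied without explicit theta/omega_L. Inside the driver the combined
score is evaluated through a precomputed table of candidate atom-pair
distance bins (all decoy atoms live on the template), so one evaluation
is a masked gather instead of a decoy rebuild; the fast path is asserted
equal to the explicit build-then-score route in the tests.

## Training utilities

* `train_omega` maximizes over omega > 0 the number of
  positive/negative pairs with `omega * (L_pos - L_neg) < G_neg - G_pos`
  (a positive-slope line with the most points above it). The count is
  piecewise constant with breakpoints at the positive ratios y/x, so
  scanning one candidate per open interval is exact; ties resolve to the
  smallest maximizing candidate. A dense-grid brute force confirms the
  count on random point sets.
* `select_negatives` clusters candidate alignments greedily by
  match-state Jaccard overlap (threshold 0.8), keeps representatives
  whose quality falls more than 0.2 below the reference, and samples a
  fixed number under a seed.
* `select_theta` sorts (normalized local score, quality gap) records and
  returns the largest score whose running mean of gaps stays below the
  limit (default 0.1) — the easy-pair gate above.
* `tm_quality` is a TM-score-style measure: over matched C-alpha pairs,
  rigid superpositions seeded on sliding fragments of halving lengths,
  refined on the sub-d0 pairs until stable, keeping the maximum of
  `(1/L_target) * sum 1/(1+(d_i/d0)^2)` with L_target the query length
  and `d0 = max(1.24 (L_target-15)^(1/3) - 1.8, 0.5)`. It is
  re-implemented (rather than shelling out to the external program) to
  keep the package self-contained; rigid invariance and the value 1.0 on
  self-pairs are asserted.
* `partial_discrimination` runs the partial-structure experiment: excise
  the same seeded residue subset from a native structure and all its
  decoys, and report per keep-fraction how often the native is the strict
  energy minimum.

## Synthetic data

The generators build ideal-geometry backbones (standard bond lengths and
angles; helix phi/psi = -57/-47, strand -120/+120, mixed alternating
7-residue runs), with ideal Cbeta placement and uniformly sampled residue
types. Threading pairs are derived from a common 48-residue parent: the
template drops one interior segment (becoming query insertions), the
query drops a disjoint one (template deletions, default 3 residues each),
the query sequence is mutated to a target identity (default 0.6 —
mid-range sequence identity with conserved structure, the regime
threading targets), coordinates are perturbed with 0.3 Å Gaussian noise,
and the profile is a softened point-mass on the query sequence. Predicted
query annotations are taken from the true query structure, i.e. a
perfect-predictor stand-in. The rescue fixture is fully hand-constructed:
a 6-residue template whose only long-range Cbeta contact rewards the
reference alignment through a planted table entry while the profile
slightly prefers a shifted alignment.

What these fixtures do *not* emulate: real side-chain packing, realistic
contact densities, predictor errors, or evolutionary profile structure.
Passing tests therefore demonstrate algorithmic correctness (exact
optima, set equalities, invariances, contract properties) — not expected
accuracy on real proteins, which depends on trained weights and a real
potential.

## Numerical choices and edge cases

* Alignments with zero match states score +inf (both items are undefined
  on an empty decoy); the DP still considers the all-gap alignment on the
  raw scale so tiny instances remain exactly comparable to enumeration.
* Traceback ties: prefer match, then template-gap, then query-gap; argmin
  reconstruction recomputes candidate minima instead of comparing
  floating-point differences.
* Distance bin lookup uses half-open bins with `searchsorted(...,
  "right") - 1`; energies are identically zero at and beyond r_cut by
  construction.
* `excise_random` keeps `round(fraction * size)` residues and refuses to
  leave zero; the same sub-seed is used for native and decoys so the
  excised index sets coincide.
* Secondary-structure assignment smooths H/E runs shorter than 3 to coil;
  terminal residues with undefined dihedrals get 'C' and the undefined
  structural-alphabet letter '-'.
* Burial uses the chain-median contact number as its threshold, so the
  two classes are balanced per chain by construction.
* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; derived seeds stay below 2^31.

## Known limitations

* The structural alphabet is a fixed 16-cell (phi, psi) grid — a stand-in
  that preserves the role of local backbone-shape compatibility without
  an external conformational-letter model; it is pluggable.
* The potential is distance-only; orientation-dependent terms are out of
  scope.
* Local weights, theta and omega_L shipped here are not fitted to any
  real benchmark; retraining utilities are provided instead.
* The DP is a plain Python/NumPy implementation adequate for chains of a
  few hundred residues; it is not banded or vectorized.
* Multi-chain templates, mmCIF, and NMR multi-model files are not
  supported; local (Smith-Waterman) alignment semantics are not offered.

## Problem sizes used by the checks

The exhaustive oracles run at m, n <= 6 (alignment spaces up to 924
members; 200 random instances for the DP check), neighborhood set
equality at m <= 5, n <= 4, k <= 3, the decoy contract on 1000 random
alignments of a 20-residue chain, potential recovery on 60k simulated
pair observations plus 100k uniform-ball pairs, and the trainer oracle on
100 random point sets against a 10^4-point grid. These sizes keep the
whole suite and the acceptance script within a few minutes on one CPU
while every check remains an exact (not sampled) comparison at its size.
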