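# Methods

This note documents the models implemented in `probmsa`, the parameter
defaults and why they were chosen, the numerical conventions, and what the
synthetic-family tests do and do not demonstrate.

## Pairwise posterior models

### Pair hidden Markov model

The pair-HMM has five states: one match state M emitting residue pairs, and
two insert-state pairs (X/Y short, X/Y long) emitting single residues, the
standard topology of the ProbCons lineage. Transitions are parameterised by
a short-gap open/extend pair (0.01195 / 0.39658) and a long-gap open/extend
pair (0.00801 / 0.89888), with an initial state distribution that puts
most mass on M and the long-gap states. These magnitudes follow
ProbCons-family conventions; none of them is fitted here, and all can be
overridden through the `key = value` parameter file (`--params`).

Match emissions are a joint distribution over residue pairs derived from a
log-odds substitution matrix: `p(a,b) ∝ q_a q_b 2^(s(a,b)/2)` with BLOSUM62
scores (half-bit convention) and BLOSUM62 background frequencies,
normalised to sum to one. Insert emissions are the marginals of that joint,
which keeps the model exchange-symmetric. Ambiguity codes (B, Z, U, O, X)
map to a wildcard letter with a small background frequency (0.005) and
odds ratio 1, so they neither reward nor punish any pairing.

The posterior P(x_i ∼ y_j) is computed by forward–backward over state
paths; the model has no explicit end state, so the total probability is the
sum of forward values over all states at the terminal cell. All recursions
run in log space (log-sum-exp), so sequences of length 10⁴ cannot
underflow. The forward–backward kernels are numba-compiled and release the
GIL, which is what makes thread-based worker pools effective.

### Partition function

The second posterior comes from a Boltzmann ensemble over all affine-gap
global alignments: an alignment with total score S (substitution scores
plus `open + (k−1)·extend` per maximal gap run; a gap run in x followed
immediately by one in y counts as two runs) has weight `exp(β·S)`. Three
coupled recursions (match / gap-in-x / gap-in-y) compute forward and
reverse partition values; the posterior is
`Z_fwd(match at i,j) · Z_rev(from i,j) / Z_total`.

Defaults: GONNET1992 substitution scores with gap open −2.2, gap extend
−0.1, β = 2.0. GONNET1992 ships in units one tenth of the classic Gonnet
table, so this operating point is the conventional Probalign choice
(temperature 5 with −22/−1 gaps on the 10× table) rescaled. As β → 0 the
posterior tends to the fraction of global alignments containing each pair
(verified against a counting oracle); as β grows it concentrates on the
optimal alignment.

### Combination, MEA and distances

The two posteriors are merged entrywise as a root mean square. Note a
type-level subtlety: each individual posterior has row and column sums
bounded by 1, but the RMS of two such matrices may exceed 1 in a row sum
(RMS ≥ mean), so only the per-entry bound is enforced on combined
matrices.

The MEA score is the maximum total posterior over monotone matchings,
computed by Needleman–Wunsch with zero gap cost. The recursion's left
dependency collapses into a running maximum, so each DP row is a vectorised
prefix-max. Distance is `1 − MEA/min(l_x, l_y)`, clamped to [0, 1].

## Sparse representation and filtering

Posterior matrices are stored compressed by rows — per-row sizes, row
offsets and a flat (column, value) element array — which is exactly CSR;
the implementation is backed by `scipy.sparse.csr_matrix` and exposes the
sizes/offsets/elements views. Conversions (sparsify, densify, transpose)
are bit-exact round trips.

Two filters exist:

* **static** — drop elements below τ (default 0.01, `--threshold`). On
  typical protein pairs this retains a few percent of the positive entries.
* **adaptive** — keep the ⌈f·N⌉ largest elements of each matrix, where N is
  the matrix's own positive-element count (default f = 0.15,
  `--fraction`). Ties at the cutoff are resolved in (row, column)
  lexicographic order, earliest kept, so the retained count is exact and
  deterministic.

The rationale for the adaptive mode: a global τ removes a much larger
*fraction* of evidence from distant pairs (whose posteriors are flat) than
from close ones, and that asymmetric loss is precisely where accuracy is
scarcest. The per-matrix fraction equalises the loss.

**Where the adaptive filter applies.** Only at stage I. Applying a
top-fraction filter again after each consistency round would compound to
f^(1+rounds) of the original evidence — with the defaults, under 0.4% after
two rounds — and measurably collapses accuracy on divergent families. In
accurate mode the consistency rounds therefore apply no additional value
threshold; the element count still decreases every round because the
no-fill rule only ever shrinks support. In static mode the same τ is used
at stage I and after each round.

## Consistency transformation

Each round relaxes every pairwise matrix through all third sequences with
ClustalW weights (formula in the README), entirely on sparse operands, and
always against a snapshot of the pre-round table — results are therefore
independent of pair processing order and worker count. The table stores
both orientations of every pair (S_yx is the exact transpose of S_xy), so a
single sparse-product routine serves all index orderings. Filtering is
applied once per round, after the weighted average. The sparse pathway is
validated cell-by-cell (1e-9) against an independent dense-numpy reference
implementation.

## Guide tree and weights

Classic size-weighted UPGMA: merge the closest pair, node height = half the
minimum distance, inter-cluster distances updated by the size-weighted
average. Equal minima break towards the smallest (i, j) cluster indices, so
construction is deterministic. The tree is ultrametric by construction
(checked to 1e-9 in tests).

ClustalW weights divide each branch length by the number of leaves below it
and sum these shares along each leaf's root path, then normalise to mean 1
(the relaxation formula is scale-invariant when numerator and denominator
share the scale; mean 1 keeps magnitudes tame). Zero-length *leaf* branches
(duplicate sequences) are floored at 1e-9 so duplicates keep strictly
positive weight; zero-length internal branches contribute exactly zero so
that symmetric topologies yield exactly equal weights.

## Progressive alignment and refinement

Profiles are matrices of 1-based residue indices per column (0 = gap). The
expected match score between profile columns is the weighted average of the
relaxed posteriors over all cross pairs; gap cells index the posterior's
zero boundary and contribute exactly 0. Profile pairs are merged by the
same zero-gap-cost recursion, row-wise, with a deterministic traceback
(diagonal > consume-left-profile > consume-right-profile on ties), and
all-gap columns are removed after every merge.

Refinement draws r = 10 random horizontal splits: each row joins side A
with probability 1/2 (resampled while a side is empty), both halves drop
all-gap columns, and the two profiles are realigned and accepted
unconditionally — replacement, not hill-climbing. The RNG is numpy's PCG64
seeded from `--seed`, so runs reproduce across platforms.

## Scoring

SP counts reference residue pairs (over reference columns with ≥ 2
residues; gap–residue and gap–gap pairs never count) reproduced in the
test alignment; TC counts reference columns whose complete residue content
co-occurs in a single test column (extra residues in that test column do
not disqualify it — the reference content is still aligned together).
Under this convention TC = 100 implies SP = 100. A core-column mask
restricts scoring to annotated columns when provided.

## Synthetic families

The generator evolves an ancestor (residues drawn uniformly over the 20
amino acids) along a balanced, star or random binary tree. Per branch, each site substitutes with probability `sub_rate`
(uniform replacement over the other 19 letters — a Jukes–Cantor-style
process); indel events occur per site with probability `indel_rate`
(half insertions, half deletions) with geometric lengths (mean
`mean_indel`). Homology is tracked by explicit column identities, so the
emitted reference alignment is exact, and the core mask covers all columns.
The twilight-zone preset (star topology, sub_rate 0.5, n = 8, length 100)
lands below 30% mean pairwise identity.

What this does *not* emulate: empirical amino-acid exchangeabilities
(substitutions are uniform), rate heterogeneity across sites, conserved
blocks/domain structure, and compositional bias. Passing tests therefore
demonstrate algorithmic correctness and the *relative* value of consistency
and adaptive filtering under a clean evolutionary model — not benchmark
accuracy on real protein families.

## Problem sizes and defaults

Default configuration: 2 consistency rounds, 10 refinement iterations,
static τ = 0.01, adaptive f = 0.15 (accurate mode), seed 0, 1 worker.

Test-suite problem sizes are chosen so every oracle is exhaustive where it
claims to be: posterior enumeration oracles cover all sequence pairs of
lengths ≤ 2 over a reduced 4-letter alphabet plus all length combinations
and 200 random pairs up to length 4 (path enumeration grows
super-exponentially beyond that); the consistency dense oracle runs 100
random instances with up to 8 sequences of length ≤ 12; pipeline
invariants run on 50 families with up to 10 sequences of length ≤ 120.
`scripts/acceptance.py` uses 12 twilight families of 8×100 per
configuration. These sizes keep the full verification cycle at desk scale
while leaving every algorithmic path exercised.

## Known limitations

* HMM and partition parameters are inherited conventions, not fits; real
  protein families may prefer retrained emissions.
* Double precision throughout; platforms with different FMA behaviour could
  in principle produce last-ulp differences in posteriors (the
  determinism contract is per-platform).
* UPGMA is the classic size-weighted variant; no attempt is made to mirror
  any particular tool's tie-breaking beyond the documented rule.
* The aligner targets tens of sequences at desk scale; it is quadratic in
  sequence count at stage I and cubic in the consistency stage.
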