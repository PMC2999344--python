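# Methods

## Problem setting

Given a target protein, a group A of functionally identical proteins and a
group ~A of sequence-related but functionally negative proteins, the package
ranks target residues by how strongly they separate the two groups: a
residue that is conserved toward A and divergent from ~A is a candidate
functional residue. The two group alignments are inputs (built by any MSA
tool); this package aligns the target *to* the two profiles and votes.

## Three-profile alignment

### Objective

An alignment of profiles P₁, P₂, P₃ (m_max columns after gap insertion) is
scored as the sum over its three pairwise projections. Substitution terms
use the weighted sum-of-pairs column score Sp defined in the README; pairs
touching an intra-profile gap contribute zero, because alignment-level gap
columns are already charged GOP/GEP and charging ragged group alignments
again would penalize them twice.

Gap costs are affine and charged per pairwise projection: a maximal run of L
residue-vs-gap columns costs GOP + (L−1)·GEP. A projected gap-vs-gap column
(both profiles silent in that projection, e.g. shape --r seen by the (1,2)
projection) scores zero and pays nothing. We use the quasi-natural
convention: whether a residue-vs-gap column opens (GOP) or extends (GEP) a
run is decided by the immediately preceding column alone, so a run that
resumes after a gap-vs-gap column pays a fresh GOP. This is the standard
convention that makes the objective exactly decomposable over consecutive
column pairs; the fully "transparent" alternative (gap-gap columns neutral
to run identity) cannot be represented with one dynamic-programming state
per column shape, because a gap-gap column erases which side of the
projection the run was on.

### Dynamic program

Seven score layers, one per non-empty column shape (rrr, rr-, r-r, -rr,
r--, -r-, --r), indexed by the number of columns consumed from each
profile; a virtual start state seeds the origin. Each cell maximizes over
the 7 (+start) predecessor states, adding the substitution terms of the new
column and the per-projection gap charges determined by the
(predecessor-shape, new-shape) pair. Complexity O(L₁·L₂·L₃·7·8) time,
O(L₁·L₂·L₃·8) memory; the kernel is compiled with numba and aligns three
length-120 profiles in about one second on one CPU (length 150 well within
minutes). Ties are broken deterministically by preferring shapes in the
order rrr > rr- > r-r > -rr > r-- > -r- > --r, both for predecessors and at
the terminal cell, so repeated runs yield byte-identical alignments.

With `end_gaps_free` set, gap columns in a projection are free while the
gapped profile has consumed none, or all, of its columns — i.e. leading and
trailing runs cost nothing. Default is off (terminal gaps priced like
internal ones): the simpler contract, appropriate when the three inputs
cover comparable domains.

Boundary initialization: only the origin is reachable at zero columns; all
first columns open their projections' gap runs (subject to end-gap
freedom). No transition is forbidden beyond shape feasibility — immediate
alternation between gap shapes is legal and priced as a side switch (new
GOP), which the brute-force oracle confirms is consistent with the
objective.

### Verification

`brute_force_align` enumerates every legal sequence of column shapes (DFS,
profiles capped at 6 columns — the count of shape sequences grows like the
3-D Delannoy numbers, ~7·10⁵ at lengths 4/4/4) and scores each with the
same column-local objective; `rescore` recomputes the objective of a
finished alignment from its columns alone, deriving each column's shape
from content. The test suite asserts DP = brute force on randomized
instances (random symmetric matrices with dominant diagonal, random
GOP ≥ GEP, intra-profile gaps, end-gap freedom on and off), projection
identity (stripping inserted gap columns recovers the inputs), permutation
symmetry of the score, and rescore-traceback consistency; plus a degenerate
reduction: with P₃ a copy of a single-sequence P₂ and zero gap costs, the
three-way optimum equals the optimal pairwise alignment under doubled
substitution scores plus the P₂ self-match constant, checked against an
independent pairwise recursion.

## Voting

Votes are unweighted: the alignment stage may weight sequences, but each
(A-sequence, ~A-sequence) pair casts exactly one vote per column, so the
T-score of a column with m A- and n ~A-sequences is a sum of m·n integer
matrix differences. Two gap rules are provided:

* `any_gap_zero` (default): a column where any sequence of any group shows
  a gap is reported with raw T-score exactly 0 and flagged. This treats
  incomplete columns as uninformative rather than letting partial sums
  masquerade as evidence.
* `target_gap_skip`: only target-gap columns are unreported; group gaps
  zero their own matrix term, the column is still scored.

Normalization is min-max to 0–100 over all reported entries, gap-zeroed
ones included (they are real entries of the score vector, and excluding
them would shift every other score). A degenerate table (all raw scores
equal) maps to all zeros with a logged warning rather than an error.
Selection uses strict inequality ("over" the threshold, default 60); with
two A groups, each vote is normalized separately and positions must exceed
the threshold in both to survive merging — merging operates on selections,
not on pooled scores, so per-vote normalization is the consistent choice.

## Substitution matrices

The built-in BLOSUM62 is the canonical NCBI integer half-bit table, vendored
in NCBI flat format and parsed by the same reader that accepts user matrix
files; tests cross-check every cell against biopython's copy. Symbols
outside a matrix's alphabet are a hard error, never a silent zero — a
silently zeroed lookup would corrupt T-scores undetectably. Ambiguity codes
B/Z/X and '*' score from the matrix's own rows. Gap characters are handled
by the alignment and voting layers, never looked up.

## Synthetic families

`favat.synth` generates the study design the method expects: a random
target (uniform over the 20 standard residues), an A group mutated at
exactly round((1−identity_A)·L) non-planted positions (defaults: 4
sequences at 35% identity), and a ~A group mutated at every planted
position plus enough background positions to reach its band (4 sequences at
65%). Planted substitutions in ~A are drawn from residues with BLOSUM62
score ≤ 0 against the target residue, guaranteeing the contrast the
statistic amplifies; background substitutions are uniform over the 19
alternatives. Identity is exact by construction (matches over target
length). Optional indels (`indel_rate`, default 0) produce unaligned
sequences for workflows that pre-align groups externally; default fixtures
are natively aligned and exactly analyzable.

What the generator does **not** emulate: phylogenetic correlation between
group members, realistic substitution processes, domain architecture, or
alignment error in the input profiles. Passing the recovery test therefore
shows that the pipeline amplifies a planted conservation contrast under
idealized divergence — not that it is robust to misaligned or
phylogenetically structured real groups.

### Calibration of the generator-based tests

* Feature recovery: 20 seeded families (length 120, 6 planted positions,
  4+4 sequences, 0.35/0.65 identity bands, no indels); all six planted
  positions must rank in the top 10 normalized scores in ≥ 90% of seeds.
* Null behaviour: with no planted positions and equal identity bands the
  per-run exceedance rate of threshold 60 is ~0.3 (min-max normalization
  guarantees scores up to 100 in every run, so *some* positions always
  exceed 60); the meaningful null statement is positional: no single
  position exceeds 60 in more than half of the replicates. 64 replicates
  keep the binomial replication noise (sd ≈ 0.06) clearly below that 0.5
  bound; at 20 replicates the noise ceiling alone reaches ~0.55 and the
  bound would be uninformative.

## Numerical and interface choices

* Scores are float64 throughout the DP; all worked-example quantities are
  integer-valued and compared exactly, DP-vs-oracle equality at 1e-9.
* Default weighting "uniform" (1/m) keeps Sp on the scale of one
  substitution score for any group size, so a single GOP/GEP default
  (10 / 0.5) behaves consistently; "unit" reproduces plain unweighted
  sum-of-pairs.
* Columns are 0-based internally; every report is 1-based in ungapped
  target coordinates with the residue name (e.g. His67).
* Reports are TSV with '#' parameter headers; alignments are single FASTA
  files with `favat_group=` tags so the voting stage can be re-run from the
  emitted alignment alone.
* CLI exit codes: 0 success, 2 configuration error, 3 data error. A YAML
  config file, when given, overrides command-line flags.

## Known limitations

* The aligner is exact but cubic; three profiles of length ~500 are
  feasible (minutes, ~4 GiB for the DP layers) but long multi-domain
  proteins are not the intended scale, and no heuristic/banded mode is
  provided.
* No statistical significance is attached to T-scores; the threshold is a
  rank cutoff, not a p-value.
* Voting assumes the three-way alignment is correct; errors in the input
  group alignments propagate unexamined.
* Only protein alphabets are supported.
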