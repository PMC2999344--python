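# favat

Functional-residue prediction for proteins whose phylogeny does not track
their function. In several enzyme superfamilies (the amidohydrolases being
the classic case: imidase, hydantoinase, dihydroorotase, allantoinase and
their inactive relatives), a target enzyme's closest sequence relatives can
*lack* its activity while distant relatives share it. Plain multiple
sequence alignment then highlights the wrong residues: conservation follows
sequence similarity, not function.

`favat` exploits that discrepancy instead of being confused by it. The user
supplies three inputs:

* a **target** sequence,
* an aligned group **A** of proteins that share the target's functional
  property despite low sequence identity, and
* an aligned group **~A** of proteins that are highly similar in sequence
  but functionally negative.

The package (1) aligns the target simultaneously to both group profiles by
three-way dynamic programming, and (2) scores every target residue by
substitution-matrix voting over the aligned columns.

## Model

**Three-profile alignment.** Profiles are scored column-against-column with
the weighted sum-of-pairs substitution score

    Sp(i, j) = Σ_a Σ_b  W_a · W_b · M[ r₁(a,i), r₂(b,j) ]

(M a substitution matrix, BLOSUM62 by default; pairs involving an
intra-profile gap contribute 0). An alignment column may take any of the
seven shapes rrr, rr-, r-r, -rr, r--, -r-, --r, and the objective is
Sp(1,2) + Sp(1,3) + Sp(2,3) per column with affine gap costs
(GOP + (L−1)·GEP for a length-L run) charged independently in each pairwise
projection, quasi-natural convention. The optimum is found exactly by a
seven-state dynamic program, one score layer per column shape — the
classical S/E/F/G/H/I/J recursion — in O(L₁·L₂·L₃·7) time. A brute-force
enumerator over all legal column-shape sequences provides an independent
optimality oracle on small inputs.

**Voting.** At each aligned column k where the target shows residue t, every
(A-sequence a, ~A-sequence b) pair casts one vote

    V_k(a,b) = M[t, A(a,k)] − M[t, ~A(b,k)]

positive when t resembles the functional group more than the
non-functional one. The m·n votes sum to the raw T-score T_k; a column with
a gap in any sequence of any group scores 0 (default rule). T-scores are
min-max normalized,

    T'_k = (T_k − min T) / (max T − min T) × 100,

and residues with T' above a threshold (default 60, strict) are reported.
With two A groups, two votes are run and only positions above threshold in
**both** are kept (`merge_votes`).

## Worked example

Generate a synthetic family with six planted functional positions
(conserved in a remote A group at 35% identity, substituted away in a close
~A group at 65% identity), then run the pipeline:

```sh
favat fixture --seed 1 --length 120 --planted 6 --outdir fam
cat fam/truth.txt          # planted positions: 6 29 35 39 48 86
favat run --target fam/target.fasta --a fam/group_A.fasta \
          --na fam/group_notA.fasta --outdir out
```

which prints

```
vote 1: 23 candidates over 60.0
  Y48	100.0
  D29	98.9
  D6	96.6
  N86	93.2
  M39	92.0
  I35	88.6
  T90	70.5
  ...
```

The six planted positions (Tyr48, Asp29, Asp6, Asn86, Met39, Ile35) are
exactly the six top-scoring residues — the voting statistic amplifies the
conserved-in-A / substituted-in-~A contrast far above the background of
ordinary sequence divergence. `out/scores.tsv` holds the full per-residue
table (position, residue, raw and normalized T-score, gap flag, selected
flag) and `out/alignment.fasta` the three-way alignment; `favat vote
--alignment out/alignment.fasta` reproduces the scores from the alignment
alone. Subcommands `align`, `vote`, `run` and `fixture` expose the stages
separately; see `favat --help`.

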