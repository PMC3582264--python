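# adpkit — algebraic dynamic programming over sequences

`adpkit` is a library (plus a small CLI) for writing dynamic programming
algorithms over one or two sequences *declaratively*, in the algebraic
discipline of DP (ADP).  Instead of hand-deriving recurrences with their
subscript arithmetic, you describe:

* a **tree grammar** 𝒢 — the search space: every candidate solution is a
  tree of function symbols spelling the input x at its leaves;
* an **evaluation algebra** A — implementations of those function symbols
  plus an objective (choice) function h acting on lists of answers;
* optionally, **algebra products** combining two analyses into one.

The engine then evaluates 𝒢(A)(x): it tabulates subproblems (half-open
subwords, or pairs of subwords for two-track grammars), applies h at marked
nonterminals, and supports co-optimal, k-best and stochastic backtracing.
Provided Bellman's principle holds — h distributes over the scoring
functions — this equals evaluating every candidate and choosing once, which
is exactly what the bundled brute-force oracle computes and what the test
suite verifies exhaustively on small inputs.

The intended users are bioinformaticians who build DP tools: alignment
variants, RNA structure analyses, HMM/SCFG-style scoring.  Three worked
applications ship as tested instances:

* **pairwise global alignment** (Needleman–Wunsch search space; unit and
  weighted edit costs, alignment printing, counting),
* **Nussinov-style RNA folding** (base-pair maximization over non-crossing
  structures, dot-bracket output, classified counting),
* **banded flowgram alignment** (pyrosequencing reads as frames of four
  flow values; frame-wise gaps, terminal indels, a diagonal band filter).

## A worked example

```python
import adpkit as k

ali = k.alignment_app()                      # signature + grammar + algebras
k.solve(ali.grammar, ali.algebras["unit"], ("DARLING", "AIRLINE"))
# [3]                       <- minimal number of unit-cost edit operations

nus = k.nussinov_app()
k.solve(nus.grammar, nus.instance("cooptnum"), "GCGC")
# [(2, 2)]                  <- 2 base pairs at most, achieved by 2 structures

k.backtrace(nus.grammar, nus.instance("cooptimals"), "GCGC")
# [(2, '()()'), (2, '(())')]   <- the two co-optimal structures themselves

prod = k.overlay(ali.algebras["count"], ali.algebras["print"])
k.sample(ali.grammar, prod, ("A", "C"), 3, seed=7)
# [('A', 'C'), ('-A', 'C-'), ('A', 'C')]  <- uniform draws from the 3 alignments
```

The same analyses from the shell:

```bash
$ adpkit fold rna.fa --product "bpmax*print"
2 ()()
2 (())
$ adpkit align pair.fa --algebra unit
3
$ adpkit flowalign flows.txt --band 10
0 8 0 2
```

The flowgram line reports the instance `RKdenoiser = score * (length %
mismatch % seqlen)`: the optimal alignment score followed by the alignment
length, mismatch score and mismatch length of one optimal candidate —
frame gaps cost 15.0·4.0 under `score`, and the auxiliary algebras use
rounded flow values (each flow value estimates a homopolymer run length).

Products are written with the operators `*` (lexicographic / classified
DP), `%` (Cartesian), `.` (take-one), `/` (interleaved) and `|` (overlay
for sampling); `suchthat(...)` attaches a semantic filter after the choice.

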