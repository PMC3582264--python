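# Methods

## The model

`adpkit` implements the algebraic discipline of dynamic programming (ADP)
over sequence data.  A problem is specified by three components over a
shared *signature* (a set of function symbols with per-track argument
sorts, plus one choice symbol):

* A **tree grammar**: an axiom and nonterminals, each a list of tree-pattern
  alternatives over terminal parsers (`EMPTY`, `CHAR`, `CHAR(c)`, `REGION`,
  `SEQ`, `VOID`) and nonterminal references.  For an input x, the candidate
  trees derivable from the axiom that spell x at their leaves form the
  search space.  Two-track grammars consume two sequences; terminal
  arguments are per-track tuples whose `void` slots consume nothing.
* An **evaluation algebra**: an implementation per function symbol plus a
  choice function h on answer *lists* (answers are ordered lists, not sets;
  duplicates are preserved unless an algebra is set-valued).  Property
  flags — unitary, set-valued, selective, enumerative, synoptic — describe
  h and gate product admissibility; `verify_algebra_properties` checks the
  sample-decidable ones dynamically (synoptic is declared-only).
* Optional **algebra products** over pair answers: Cartesian (`%`, both
  unitary, components optimized independently), lexicographic (`*`,
  per-class analysis; classified DP when the first algebra classifies),
  take-one (`.`, one candidate per class), interleaved (`/`, a second
  global selection across class survivors) and overlay (`|`, forward pass
  under the first algebra, second materialized only while sampling).
  `suchthat` removes answers failing a predicate after each choice
  application; the predicate must be pruning-safe, which is documented,
  not checked.

The reference semantics is: enumerate all candidates, evaluate each
bottom-up, apply h once.  The engine instead applies h at choice-marked
nonterminals over tabulated subproblems; the two agree exactly when
Bellman's principle holds (h distributes over the scoring functions).
`check_bellman` is a seeded dynamic falsifier of that property — it compares
engine and oracle on sampled small inputs and reports the first
counterexample; passing is evidence, not proof.  Static product analysis is
out of scope by design.

## Engine

Evaluation is recursive top-down with memoization, chosen over bottom-up
cell scheduling because it needs no dependency ordering and only touches
reachable cells (for suffix-shaped grammars like alignment this is O(n²) of
the O(n⁴) subword-pair space).  Subwords are 0-based half-open `(i, j)`;
two-track subproblems are span tuples.  Split loops are bounded by a
least-fixpoint *yield-size analysis* (terminal yields, `minsize`/`maxsize`
tightening, elementwise min/max over alternatives, sums over concatenation;
the max fixpoint is iteration-capped and diverging entries become ∞).

Deterministic candidate order: alternatives in textual rule order, split
points left-to-right (the first argument takes the smallest admissible span
first), earlier arguments varying slowest.  Take-one products and
single-candidate backtraces resolve ties by this order.

*Table design*: `all` tabulates everything; `auto` uses the safe greedy
rule — tabulate every nonterminal on a dependency cycle or referenced from
more than one pattern position — which guarantees each subproblem is
evaluated at most once; a user set is honored with a warning when a cycle
nonterminal is omitted.  Answers are invariant across modes (tested).

*Diagnostics*: unknown symbols, arity/sort mismatches (with the offending
nonterminal and function named), unreachable and unproductive nonterminals,
and ε-cycles (a nonterminal reaching itself with no consumption, detected on
the zero-consumption edge graph) are fatal and block solving.

*Backtracing*: the forward pass tabulates only the scoring algebra; the
backward pass re-parses with the pair product, pruning first components
that are absent from the forward tables, so only optimal sub-solutions are
expanded.  Co-optimal reporting is the default; `co_optimal=False` switches
to take-one semantics.  k-best generalizes a unitary choice to the best k
distinct values by iterated extraction (apply h, remove the winner,
repeat), which works for any unitary selective h without knowing its
ordering.  Stochastic backtracing (overlay products) requires unitary
synoptic non-negative forward weights: each descent chooses among a cell's
local derivations with probability proportional to the weight the forward
algebra assigns them, so count weights sample candidates uniformly; a
numpy `Generator` seeded by the caller fixes all randomness.

*Numerics*: answer equality for class keys, pruning and tie detection uses
a canonical form that rounds floats to 9 decimals (an absolute tolerance of
1e-9 against summation-order noise).  Rounding of flow values is half away
from zero, `floor(x + 0.5)` for the non-negative values that occur.

*Deep inputs*: recursion depth grows linearly with input length, so solves
on inputs longer than 150 symbols run on a dedicated worker thread with a
512 MiB stack and a raised recursion limit rather than an explicit work
stack — the same contract (no host recursion-limit failures on long
inputs) with far less machinery; the engine code stays a direct rendering
of the semantics.

## Shipped applications and their parameters

* **Alignment** (two-track).  `unit`: equal-character `rep` costs 0, any
  other edit 1, minimized — edit distance, which scores the worked
  column-wise DARLING/AIRLINE candidate at 3.  `score`: mismatch 3, gap 4.
  `print` pads both sequences with `-`.
* **RNA folding** (single-track).  Grammar with empty / unpaired-first /
  paired-first cases; the split-pair shape makes derivations unambiguous,
  so counting equals structure counting.  `basep` guards pairing; the
  default complementary set is {A-U, G-C, G-U} (wobble included) and is
  configurable — the applications only presuppose "complementary", not a
  specific set.  `bpmax` adds 1 per pair and maximizes; `pairclass` uses
  the same scores with a deduplicating identity choice, making it a
  classifier for classified DP.
* **Flowgram alignment** (two-track over floats).  One `CHAR` consumes one
  flow value; `del`/`ins` gaps are whole frames (`REGION` with
  `minsize(4)`/`maxsize(4)`); `ti`/`td` consume a terminal suffix via `SEQ`
  and are scored 0 in all algebras, since flowgrams may differ in length
  and only an end gap is plausible.  `score` charges `score_table(a, b)`
  per replacement and 15.0·4.0 per frame gap.  The mismatch table is
  injectable (TSV or callable); the default `|round(a) − round(b)| · 7.5`
  is this package's own placeholder scaled to the frame-gap cost, and every
  exact-value test injects an explicit table or uses the rounding algebras.
  `length` counts alignment columns (`rep`/`del`/`ins` add 1, `nil`/`ti`/`td`
  add 0) with a minimizing choice — any unitary selective choice works
  because it rides along a lexicographic product.  `banded(w, lpad, rpad)`
  accepts subproblems with `|i₁ − i₂| ≤ w` and widens near both sequence
  ends by the pads (defaulting to w); the pads are this package's
  parameterization of end-widening, and a band at least the input length
  reproduces the unbanded result exactly (tested).  `SEQ` and `REGION` have
  minimum yield 1: an empty terminal insertion would duplicate `nil` and
  make counting ambiguous.

## Synthetic data

`generate_sequence`/`generate_pair` produce uniform sequences and mutated
copies (per-position substitution rate; indel rate split evenly between
deletion and insertion).  `ideal_flowgram` encodes one frame per
homopolymer run (flow order T, A, C, G; the run length is the flow value);
`generate_flowgram_pair` adds zero-mean Gaussian flow noise clipped at 0
and whole-frame insertions/deletions with a given per-frame probability —
the error modes flowgram denoising must absorb.  Banding tests use
sequences of ~8 nt (flowgrams of 12–40 flow values), σ = 0.2 and frame
indel probability 0.08–0.1: realistic single-digit-percent frame error
rates at desk scale.  What the generator does *not* emulate: correlated
run-length-dependent noise, per-channel crosstalk and real mismatch score
tables; tests passing on this data show the alignment machinery is exact,
not that the default scoring is calibrated for a particular instrument.

## Test scope and problem sizes

Exhaustive engine-vs-oracle equivalence runs over all single-track inputs
of length ≤ 5 over {G,C,A,U} (1365 inputs) and all two-track pairs with
lengths ≤ 3 over {A,C} (225 pairs), for the plain algebras and all product
operators; classified-count conservation extends to all RNA inputs of
length ≤ 6 (5461 inputs).  These sizes make the brute-force oracle exact
while keeping the whole suite under a minute on one core; the oracle caps
itself at 100 000 candidates.  Sampling calibration uses 10 000 seeded
draws and a chi-square goodness-of-fit test at significance 0.01.  The
deep-input test aligns two 400-mers, past the default recursion ceiling.

## Known limitations

* Bellman violations are only detected dynamically, on sampled inputs.
* The interleaved product follows this package's documented semantics
  (per-class selection, then one global second-component selection); it is
  isolated in a single function so it can be swapped.
* The engine enumerates decompositions in pure Python; it is built for
  correctness, modularity and desk-scale experiments, not for competing
  with generated C++ on chromosome-scale inputs.
* All co-optimals are materialized as a list before output; a streaming
  backtrace is future work.
* No standalone grammar-definition surface syntax: grammars and algebras
  are constructed through the host-language API, which the applications
  module illustrates.
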