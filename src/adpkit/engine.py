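"""The tabulating forward evaluator and the backtracing schemes.

Evaluation is recursive top-down with memoization: each (nonterminal,
subproblem) cell is computed once and stored post-choice.  For every
alternative the engine enumerates all argument span decompositions that are
consistent with the yield-size bounds, applies the guarding filters first,
evaluates the arguments (memoized where tabulated), applies the
alternative's function to every value combination, concatenates across
alternatives, and applies the choice function where the nonterminal carries
the choice marker.

Deterministic order everywhere: alternatives in textual rule order, split
points left-to-right (the first argument takes the smallest admissible span
first), and argument value combinations with earlier arguments varying
slowest.  Backtraces and take-one products inherit this order.

Deep inputs: grammars like the Nussinov one recurse once per consumed
character, so long sequences exceed the host's default recursion ceiling.
Solves whose input is long are transparently run on a dedicated worker
thread with a large stack and a raised recursion limit.
"""

from __future__ import annotations

import itertools
import math
import threading
import sys
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .algebra import Algebra, SET_VALUED, SELECTIVE, SYNOPTIC, ENUMERATIVE, UNITARY
from .candidates import (
    K_CHAR,
    K_EMPTY,
    K_REGION,
    K_SEQ,
    K_VOID,
    Region,
    SlotValue,
    TerminalLeaf,
    canonical,
)
from .errors import AlgebraError, GrammarError
from .grammar import App, Grammar, NT, T, Term, table_design
from .products import PairAnswer, ProductAlgebra, lexicographic, take_one

INF = math.inf

#: Inputs longer than this run on a big-stack worker thread.
_DEEP_INPUT = 150
_DEEP_STACK_BYTES = 1 << 29  # 512 MiB of (virtual) thread stack
_DEEP_RECURSION_LIMIT = 1_000_000


@dataclass(frozen=True)
class Subproblem:
    """Per-track half-open bounds identifying one DP cell."""

    spans: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        for i, j in self.spans:
            if not 0 <= i <= j:
                raise GrammarError(f"invalid subproblem span ({i},{j})")


@dataclass
class SolveOptions:
    """Options controlling tabulation and backtracing.

    ``table_mode`` is ``"all"``, ``"auto"`` or a collection of nonterminal
    names; ``co_optimal`` selects whether backtracing reports every optimum
    or a single one; ``k`` is the number of score classes for k-best
    backtracing; ``seed`` fixes all stochastic behaviour.
    """

    table_mode: Union[str, Sequence[str]] = "auto"
    co_optimal: bool = True
    k: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise GrammarError("k must be >= 1")


class MemoTable:
    """Per tabulated nonterminal: subproblem -> post-choice answer list."""

    def __init__(self) -> None:
        self._data: Dict[tuple, list] = {}

    def get(self, key: tuple):
        return self._data.get(key)

    def put(self, key: tuple, value: list) -> None:
        self._data[key] = value

    def items(self):
        return self._data.items()

    def __len__(self) -> int:
        return len(self._data)


def _normalize_inputs(grammar: Grammar, inputs) -> tuple:
    if grammar.tracks == 1:
        if isinstance(inputs, (tuple, list)) and len(inputs) == 1:
            return (inputs[0],)
        if isinstance(inputs, (str, np.ndarray)):
            return (inputs,)
        if isinstance(inputs, (tuple, list)) and inputs and isinstance(inputs[0], (int, float)):
            return (list(inputs),)
        if isinstance(inputs, (tuple, list)) and not inputs:
            return ("",)
        raise GrammarError("single-track grammar expects one sequence")
    if not isinstance(inputs, (tuple, list)) or len(inputs) != grammar.tracks:
        raise GrammarError(
            f"grammar {grammar.name!r} expects {grammar.tracks} input sequences"
        )
    return tuple(inputs)


def compositions(i: int, j: int, bounds: Sequence[Tuple[float, float]]):
    """All splits of span (i, j) into len(bounds) contiguous chunks.

    ``bounds[k]`` is the (min, max) length of chunk k.  Enumeration order is
    deterministic: the first chunk takes the smallest admissible length
    first, recursively.  Yields tuples of (start, stop) spans.
    """
    n = len(bounds)
    if n == 0:
        if i == j:
            yield ()
        return
    lo0, hi0 = bounds[0]
    rest_lo = sum(b[0] for b in bounds[1:])
    rest_hi = sum(b[1] for b in bounds[1:])
    avail = j - i
    start = max(int(lo0), int(avail - rest_hi) if rest_hi != INF else int(lo0))
    stop = avail - rest_lo
    if hi0 != INF:
        stop = min(stop, hi0)
    size = start
    while size <= stop:
        for rest in compositions(i + size, j, bounds[1:]):
            yield ((i, i + size),) + rest
        size += 1


def match_terminal(term: Term, seq, track: int, i: int, j: int) -> Optional[SlotValue]:
    """Match one terminal parser against subword seq[i:j]; None on failure."""
    k = term.kind
    ln = j - i
    if k in ("EMPTY", "VOID"):
        return SlotValue(K_EMPTY if k == "EMPTY" else K_VOID, track, (i, j)) if ln == 0 else None
    if k == "CHAR":
        if ln != 1:
            return None
        c = seq[i]
        if term.char is not None and c != term.char:
            return None
        return SlotValue(K_CHAR, track, (i, j), c)
    if k == "REGION":
        return SlotValue(K_REGION, track, (i, j), Region(seq, i, j)) if ln >= 1 else None
    if k == "SEQ":
        return SlotValue(K_SEQ, track, (i, j), ln) if ln >= 1 else None
    raise GrammarError(f"unknown terminal kind {k!r}")


def eval_filters(filters, inputs, spans, tracks) -> bool:
    return all(f(inputs, spans, tracks) for f in filters)


class Engine:
    """One evaluation of a grammar with an algebra on concrete inputs."""

    def __init__(
        self,
        grammar: Grammar,
        algebra,
        inputs,
        opts: Optional[SolveOptions] = None,
        ignore_choice: bool = False,
        prune_first_by: Optional[Dict[tuple, Set]] = None,
    ) -> None:
        self.grammar = grammar
        self.algebra = algebra
        self.opts = opts or SolveOptions()
        fatal = [d for d in grammar.diagnostics() if d.fatal]
        if fatal:
            raise GrammarError(
                f"grammar {grammar.name!r} has fatal diagnostics: {fatal[0].message}"
            )
        if algebra.signature is not grammar.signature and (
            algebra.signature.name != grammar.signature.name
            or set(algebra.signature.functions) != set(grammar.signature.functions)
        ):
            raise AlgebraError(
                f"algebra {getattr(algebra, 'name', '?')!r} implements "
                f"{algebra.signature.name!r}, grammar uses {grammar.signature.name!r}"
            )
        self.inputs = _normalize_inputs(grammar, inputs)
        self.ignore_choice = ignore_choice
        self.prune_first_by = prune_first_by
        self.coverage = grammar.coverage()
        self.yields = grammar.yields()
        self.tabulated = table_design(grammar, self.opts.table_mode)
        self.memo = MemoTable()
        self._in_progress: Set[tuple] = set()
        self._bounds_cache: Dict[int, list] = {}

    # -- public -------------------------------------------------------------
    def solve(self) -> list:
        spans = tuple((0, len(s)) for s in self.inputs)
        tracks = tuple(range(self.grammar.tracks))
        total = sum(len(s) for s in self.inputs)
        if total <= _DEEP_INPUT:
            return self._nt(self.grammar.axiom, tracks, spans)
        return _run_deep(lambda: self._nt(self.grammar.axiom, tracks, spans))

    # -- cells --------------------------------------------------------------
    def _nt(self, name: str, tracks: tuple, spans: tuple) -> list:
        key = (name, tracks, spans)
        tab = name in self.tabulated
        if tab:
            hit = self.memo.get(key)
            if hit is not None:
                return hit
        if key in self._in_progress:
            raise GrammarError(
                f"cyclic evaluation of {name!r} on spans {spans} (epsilon-cycle?)"
            )
        self._in_progress.add(key)
        try:
            nt = self.grammar.nonterminals[name]
            out: list = []
            for alt in nt.alternatives:
                out.extend(self._alt(alt, tracks, spans, top_nt=name))
            if nt.choice and not self.ignore_choice:
                if self.prune_first_by is not None:
                    allowed = self.prune_first_by.get(key)
                    if allowed is not None:
                        out = [p for p in out if canonical(p.first) in allowed]
                out = self.algebra.choice(out)
        finally:
            self._in_progress.discard(key)
        if tab:
            self.memo.put(key, out)
        return out

    def _alt(self, node, tracks: tuple, spans: tuple, top_nt: str) -> list:
        if isinstance(node, T):
            # bare-terminal alternative (single-track helper nonterminals)
            if not eval_filters(node.filters, self.inputs, spans, tracks):
                return []
            slot_vals = self._match_tuple(node, tracks, spans)
            if slot_vals is None:
                return []
            combos = list(itertools.product(*slot_vals))
            if self.coverage[top_nt] == "slot":
                return [c[0] for c in combos]
            return [TerminalLeaf(c) for c in combos]
        return self._app(node, tracks, spans)

    def _app(self, node: App, tracks: tuple, spans: tuple) -> list:
        if not eval_filters(node.filters, self.inputs, spans, tracks):
            return []
        out: list = []
        arg_bounds = [self._node_bounds(a, tracks) for a in node.args]
        per_track_splits = []
        for ti, t in enumerate(tracks):
            i, j = spans[ti]
            bounds = [b[ti] for b in arg_bounds]
            splits = list(compositions(i, j, bounds))
            if not splits:
                return []
            per_track_splits.append(splits)
        for combo in itertools.product(*per_track_splits):
            # combo[ti][k] is the span of argument k on track ti
            arg_lists = []
            ok = True
            for k, arg in enumerate(node.args):
                aspans = tuple(combo[ti][k] for ti in range(len(tracks)))
                vals = self._arg(arg, tracks, aspans)
                if not vals:
                    ok = False
                    break
                arg_lists.append(vals)
            if not ok:
                continue
            for values in itertools.product(*arg_lists):
                out.append(self.algebra.apply(node.fname, list(values)))
        return out

    def _arg(self, arg, tracks: tuple, aspans: tuple) -> list:
        if isinstance(arg, NT):
            return self._nt(arg.name, tracks, aspans)
        if isinstance(arg, App):
            return self._app(arg, tracks, aspans)
        if isinstance(arg, T):
            slot_vals = self._match_tuple(arg, tracks, aspans)
            if slot_vals is None:
                return []
            return [TerminalLeaf(c) for c in itertools.product(*slot_vals)]
        raise GrammarError(f"unknown pattern argument {arg!r}")

    def _match_tuple(self, node: T, tracks: tuple, spans: tuple):
        """Per slot: list of SlotValues, or None if any slot fails."""
        if len(node.slots) != len(tracks):
            raise GrammarError(
                f"terminal tuple {node!r} has {len(node.slots)} slot(s) for "
                f"{len(tracks)} track(s)"
            )
        per_slot = []
        for slot, t, (i, j) in zip(node.slots, tracks, spans):
            if isinstance(slot, str):
                vals = self._nt(slot, (t,), ((i, j),))
                if not vals:
                    return None
                per_slot.append(vals)
            else:
                sv = match_terminal(slot, self.inputs[t], t, i, j)
                if sv is None:
                    return None
                per_slot.append([sv])
        return per_slot

    # -- yield bounds per pattern node -------------------------------------
    def _node_bounds(self, node, tracks: tuple) -> list:
        """Per covered track: (min, max) yield of one pattern argument."""
        cached = self._bounds_cache.get(id(node))
        if cached is not None:
            return cached
        w = len(tracks)
        if isinstance(node, NT):
            ys = self.yields[node.name].per_track
            out = [tuple(ys[ti]) for ti in range(w)]
        elif isinstance(node, T):
            out = []
            for slot in node.slots:
                if isinstance(slot, str):
                    out.append(tuple(self.yields[slot].per_track[0]))
                else:
                    from .grammar import TERM_YIELD

                    out.append(TERM_YIELD[slot.kind])
        elif isinstance(node, App):
            out = [(0.0, 0.0)] * w
            subs = [self._node_bounds(a, tracks) for a in node.args]
            out = [
                (
                    sum(s[ti][0] for s in subs),
                    sum(s[ti][1] for s in subs),
                )
                for ti in range(w)
            ]
        else:
            raise GrammarError(f"unknown pattern node {node!r}")
        self._bounds_cache[id(node)] = out
        return out


def _run_deep(fn):
    """Run ``fn`` on a worker thread with a large stack and recursion limit."""
    result: dict = {}

    def target():
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(_DEEP_RECURSION_LIMIT)
        try:
            result["value"] = fn()
        except BaseException as exc:  # re-raised on the caller's thread
            result["error"] = exc
        finally:
            sys.setrecursionlimit(old)

    old_stack = threading.stack_size(_DEEP_STACK_BYTES)
    try:
        th = threading.Thread(target=target, name="adpkit-deep-solve")
        th.start()
        th.join()
    finally:
        threading.stack_size(old_stack)
    if "error" in result:
        raise result["error"]
    return result["value"]


# -- public operations ------------------------------------------------------

def solve(grammar: Grammar, algebra, inputs, opts: Optional[SolveOptions] = None) -> list:
    """Evaluate the grammar under the algebra; returns the axiom's answers."""
    return Engine(grammar, algebra, inputs, opts).solve()


def _forward_prune_map(engine: Engine) -> Dict[tuple, Set]:
    return {
        key: {canonical(v) for v in values} for key, values in engine.memo.items()
    }


def _as_pair_product(prod) -> ProductAlgebra:
    if not isinstance(prod, ProductAlgebra) or prod.op not in ("lexicographic", "take_one"):
        raise AlgebraError(
            "backtracing expects a lexicographic or take-one product algebra"
        )
    return prod


def backtrace(
    grammar: Grammar, prod: ProductAlgebra, inputs, opts: Optional[SolveOptions] = None
) -> List[PairAnswer]:
    """Forward pass under the first algebra, backward pass building the second.

    The forward pass tabulates only the scoring algebra ``A``; the backward
    pass revisits the alternatives of each subproblem, follows exactly those
    whose recomputed ``A``-value attains the tabulated choice result, and
    builds ``B``-values along them.  With ``co_optimal`` (the default) all
    optima are reported; without it, one per score class, chosen by the
    deterministic candidate order.  The result equals solving with the full
    product.
    """
    opts = opts or SolveOptions()
    prod = _as_pair_product(prod)
    fwd = Engine(grammar, prod.left, inputs, SolveOptions(table_mode="all"))
    fwd.solve()
    prune = _forward_prune_map(fwd)
    back_prod = prod
    if not opts.co_optimal and prod.op == "lexicographic":
        back_prod = take_one(prod.left, prod.right, _checked=False)
    bwd = Engine(
        grammar,
        back_prod,
        inputs,
        SolveOptions(table_mode=opts.table_mode),
        prune_first_by=prune,
    )
    return bwd.solve()


def kbest_backtrace(
    grammar: Grammar,
    prod: ProductAlgebra,
    inputs,
    k: int,
    opts: Optional[SolveOptions] = None,
) -> List[PairAnswer]:
    """Backtrace over the k best distinct score classes.

    The scoring algebra's unitary choice is generalized to return the best
    ``k`` distinct values (apply the choice, remove the winner, repeat),
    which makes it set-valued; the backtrace then reports one entry per
    surviving class, each with its second-algebra results.  Fewer than ``k``
    classes are returned when the search space is smaller.
    """
    if k < 1:
        raise GrammarError("k must be >= 1")
    prod = _as_pair_product(prod)
    base = prod.left
    if isinstance(base, ProductAlgebra):
        raise AlgebraError("k-best backtracing needs a plain scoring algebra on the left")

    base_choice = base.choice_fn

    def kchoice(answers: list) -> list:
        remaining: list = []
        seen = set()
        for x in answers:
            key = canonical(x)
            if key not in seen:
                seen.add(key)
                remaining.append(x)
        out = []
        for _ in range(k):
            if not remaining:
                break
            best = base_choice(remaining)
            if not best:
                break
            win = best[0]
            out.append(win)
            wk = canonical(win)
            remaining = [x for x in remaining if canonical(x) != wk]
        return out

    k_alg = base.replace(
        choice_fn=kchoice,
        name=f"{base.name}_k{k}",
        properties=(base.properties - {UNITARY}) | {SET_VALUED, SELECTIVE},
    )
    kprod = lexicographic(k_alg, prod.right)
    return backtrace(grammar, kprod, inputs, opts or SolveOptions())


def sample(
    grammar: Grammar,
    prod: ProductAlgebra,
    inputs,
    n: int,
    seed: Optional[int] = None,
) -> list:
    """Stochastic backtracing: sample candidates under an overlay product.

    The forward pass tabulates the synoptic weight algebra ``A`` (counting,
    or Boltzmann-style weights); each of the ``n`` independent backtraces
    then descends from the axiom, choosing among a subproblem's alternatives
    and decompositions with probability proportional to their ``A``
    contribution, and builds the enumerative algebra ``B`` along the sampled
    derivation.  Deterministic given ``seed``.
    """
    if not isinstance(prod, ProductAlgebra) or prod.op != "overlay":
        raise AlgebraError("sampling expects an overlay product A | B")
    if n < 0:
        raise GrammarError("sample size must be >= 0")
    A, B = prod.left, prod.right
    eng = Engine(grammar, A, inputs, SolveOptions(table_mode="all"))
    root = eng.solve()
    if n == 0:
        return []
    if len(root) != 1 or not isinstance(root[0], (int, float)) or root[0] <= 0:
        raise AlgebraError(
            f"empty search space or non-unitary forward weights at the axiom: {root!r}"
        )
    rng = np.random.default_rng(seed)
    tracks = tuple(range(grammar.tracks))
    spans = tuple((0, len(s)) for s in eng.inputs)

    def cell_value(name, tr, sp) -> float:
        vals = eng.memo.get((name, tr, sp))
        if vals is None:
            vals = eng._nt(name, tr, sp)
        if len(vals) != 1:
            raise AlgebraError(
                f"sampling requires unitary forward weights; cell {name}{sp} has {len(vals)}"
            )
        return vals[0]

    def local_derivs(node, tr, sp) -> list:
        """All one-step derivations of a pattern node: trees whose leaves are
        terminal leaves or ('ref', nt, tracks, spans) placeholders."""
        if isinstance(node, T):
            if not eval_filters(node.filters, eng.inputs, sp, tr):
                return []
            slot_vals = eng._match_tuple(node, tr, sp)
            if slot_vals is None:
                return []
            return [
                ("leaf", TerminalLeaf(c)) for c in itertools.product(*slot_vals)
            ]
        if isinstance(node, NT):
            return [("ref", node.name, tr, sp)]
        if not eval_filters(node.filters, eng.inputs, sp, tr):
            return []
        out = []
        arg_bounds = [eng._node_bounds(a, tr) for a in node.args]
        per_track = []
        for ti in range(len(tr)):
            i, j = sp[ti]
            per_track.append(list(compositions(i, j, [b[ti] for b in arg_bounds])))
        for combo in itertools.product(*per_track):
            arg_derivs = []
            ok = True
            for kk, arg in enumerate(node.args):
                aspans = tuple(combo[ti][kk] for ti in range(len(tr)))
                ds = local_derivs(arg, tr, aspans)
                if not ds:
                    ok = False
                    break
                arg_derivs.append(ds)
            if not ok:
                continue
            for children in itertools.product(*arg_derivs):
                out.append(("app", node.fname, children))
        return out

    def deriv_weight(d) -> float:
        kind = d[0]
        if kind == "leaf":
            return 1.0
        if kind == "ref":
            return float(cell_value(d[1], d[2], d[3]))
        _, fname, children = d
        args = []
        for c in children:
            if c[0] == "leaf":
                args.append(c[1])
            elif c[0] == "ref":
                args.append(cell_value(c[1], c[2], c[3]))
            else:
                args.append(_weight_value(c))
        return float(A.apply(fname, args))

    def _weight_value(d):
        _, fname, children = d
        args = []
        for c in children:
            if c[0] == "leaf":
                args.append(c[1])
            elif c[0] == "ref":
                args.append(cell_value(c[1], c[2], c[3]))
            else:
                args.append(_weight_value(c))
        return A.apply(fname, args)

    def sample_cell(name, tr, sp):
        nt = grammar.nonterminals[name]
        derivs = []
        for alt in nt.alternatives:
            derivs.extend(local_derivs(alt, tr, sp))
        if not derivs:
            raise AlgebraError(f"no derivations at cell {name}{sp}")
        weights = np.array([deriv_weight(d) for d in derivs], dtype=float)
        total = weights.sum()
        if total <= 0:
            raise AlgebraError(f"zero total weight at cell {name}{sp}")
        idx = rng.choice(len(derivs), p=weights / total)
        return build_b(derivs[idx])

    def build_b(d):
        kind = d[0]
        if kind == "leaf":
            return d[1]
        if kind == "ref":
            return sample_cell(d[1], d[2], d[3])
        _, fname, children = d
        args = [build_b(c) for c in children]
        return B.apply(fname, args)

    total_len = sum(len(s) for s in eng.inputs)
    run = lambda: [sample_cell(grammar.axiom, tracks, spans) for _ in range(n)]
    if total_len <= _DEEP_INPUT:
        return run()
    return _run_deep(run)
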