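"""Brute-force reference semantics for testing.

The oracle spells out the definition of the search space directly: it
exhaustively enumerates every candidate tree the grammar derives on the
input, evaluates each with the algebra's functions, and applies the choice
function exactly once to the full list.  No tabulation, no per-nonterminal
choice, no pruning — this is the semantics the optimized engine must agree
with wherever Bellman's principle holds.

Terminal matching, filter evaluation and split enumeration are shared with
the engine so that search-space membership has a single source of truth.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, List, Optional

import numpy as np

from .candidates import CandidateTree, TerminalLeaf, canonical, evaluate_candidate
from .engine import (
    Engine,
    SolveOptions,
    compositions,
    eval_filters,
    match_terminal,
    _normalize_inputs,
    solve as engine_solve,
)
from .errors import GrammarError
from .grammar import App, Grammar, NT, T, TERM_YIELD

INF = math.inf

#: Exhaustive enumeration is capped at this many candidates.
MAX_CANDIDATES = 100_000

#: Hard guard on constructed subtree instances (shared subtrees count once).
_MAX_NODES = 5_000_000


def enumerate_candidates(g: Grammar, inputs) -> List[CandidateTree]:
    """Every candidate tree derivable on ``inputs``, exactly once, in the
    engine's deterministic order (alternatives in rule order, split points
    left to right)."""
    fatal = [d for d in g.diagnostics() if d.fatal]
    if fatal:
        raise GrammarError(f"grammar {g.name!r} has fatal diagnostics: {fatal[0].message}")
    xs = _normalize_inputs(g, inputs)
    cov = g.coverage()
    count = 0

    memo: dict = {}

    def bump() -> None:
        nonlocal count
        count += 1
        if count > _MAX_NODES:
            raise GrammarError(
                f"enumeration exceeds {_MAX_NODES} constructed subtrees; "
                f"use the engine instead of exhaustive enumeration"
            )

    def node_bounds(node, width: int):
        # loose per-track bounds: terminals are exact, nonterminals unknown
        if isinstance(node, T):
            out = []
            for s in node.slots:
                out.append((0.0, INF) if isinstance(s, str) else TERM_YIELD[s.kind])
            return out
        if isinstance(node, NT):
            return [(0.0, INF)] * width
        subs = [node_bounds(a, width) for a in node.args]
        return [
            (sum(s[t][0] for s in subs), sum(s[t][1] for s in subs))
            for t in range(width)
        ]

    def match_tuple(node: T, tracks, spans):
        per_slot = []
        for slot, t, (i, j) in zip(node.slots, tracks, spans):
            if isinstance(slot, str):
                vals = enum_nt(slot, (t,), ((i, j),), frozenset())
                if not vals:
                    return None
                per_slot.append(vals)
            else:
                sv = match_terminal(slot, xs[t], t, i, j)
                if sv is None:
                    return None
                per_slot.append([sv])
        return per_slot

    def enum_node(node, tracks, spans, path):
        if isinstance(node, NT):
            return enum_nt(node.name, tracks, spans, path)
        if isinstance(node, T):
            if not eval_filters(node.filters, xs, spans, tracks):
                return []
            per_slot = match_tuple(node, tracks, spans)
            if per_slot is None:
                return []
            return [TerminalLeaf(c) for c in itertools.product(*per_slot)]
        if not eval_filters(node.filters, xs, spans, tracks):
            return []
        out = []
        arg_bounds = [node_bounds(a, len(tracks)) for a in node.args]
        per_track = []
        for ti in range(len(tracks)):
            i, j = spans[ti]
            per_track.append(list(compositions(i, j, [b[ti] for b in arg_bounds])))
        for combo in itertools.product(*per_track):
            arg_lists = []
            ok = True
            for k, arg in enumerate(node.args):
                aspans = tuple(combo[ti][k] for ti in range(len(tracks)))
                vals = enum_node(arg, tracks, aspans, path)
                if not vals:
                    ok = False
                    break
                arg_lists.append(vals)
            if not ok:
                continue
            for children in itertools.product(*arg_lists):
                bump()
                out.append(CandidateTree(node.fname, children))
        return out

    def enum_nt(name, tracks, spans, path):
        key = (name, tracks, spans)
        hit = memo.get(key)
        if hit is not None:
            return hit
        if key in path:  # zero-consumption revisit: pruned (epsilon-cycles are fatal)
            return []
        path = path | {key}
        nt = g.nonterminals[name]
        out = []
        for alt in nt.alternatives:
            if isinstance(alt, T) and cov[name] == "slot":
                if not eval_filters(alt.filters, xs, spans, tracks):
                    continue
                per_slot = match_tuple(alt, tracks, spans)
                if per_slot is not None:
                    out.extend(c[0] for c in itertools.product(*per_slot))
            else:
                out.extend(enum_node(alt, tracks, spans, path))
        memo[key] = out
        return out

    spans = tuple((0, len(s)) for s in xs)
    result = enum_nt(g.axiom, tuple(range(g.tracks)), spans, frozenset())
    if len(result) > MAX_CANDIDATES:
        raise GrammarError(
            f"search space holds {len(result)} candidates, above the "
            f"{MAX_CANDIDATES} exhaustive-enumeration cap"
        )
    return result


def reference_solve(g: Grammar, algebra, inputs) -> list:
    """Evaluate every enumerated candidate, then apply the choice exactly
    once to the full list (followed by any ``suchthat`` filter)."""
    trees = enumerate_candidates(g, inputs)
    values = [evaluate_candidate(t, algebra) for t in trees]
    return algebra.choice(values)


@dataclass
class BellmanReport:
    ok: bool
    trials: int
    counterexample: Optional[tuple] = None  # (inputs, engine answers, oracle answers)

    def __bool__(self) -> bool:
        return self.ok


def check_bellman(
    g: Grammar,
    algebra,
    input_sampler: Callable,
    trials: int,
    seed: Optional[int] = None,
) -> BellmanReport:
    """Dynamic falsifier for Bellman's principle.

    For ``trials`` sampled inputs, compares the engine's tabulating
    evaluation against the oracle as multisets; a disagreement means the
    choice function does not distribute over the scoring functions on that
    input.  Passing is evidence, not proof.
    """
    if trials < 1:
        raise GrammarError("check_bellman needs at least one trial")
    rng = np.random.default_rng(seed)
    from collections import Counter

    for _ in range(trials):
        x = input_sampler(rng)
        got = engine_solve(g, algebra, x, SolveOptions(table_mode="all"))
        want = reference_solve(g, algebra, x)
        if Counter(map(canonical, got)) != Counter(map(canonical, want)):
            return BellmanReport(False, trials, (x, got, want))
    return BellmanReport(True, trials)
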