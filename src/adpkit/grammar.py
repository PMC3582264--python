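"""Tree grammars over one or two input tracks.

A grammar names an axiom and a set of nonterminals; each nonterminal is a
list of guarded tree-pattern alternatives over terminals and nonterminal
references.  Patterns are written like function applications::

    ali = rep(<CHAR, CHAR>, ali) | del(<gap, EMPTY>, ali) | ... # h

which in this API becomes::

    Nonterminal("ali", [
        App("rep", T(CHAR, CHAR), NT("ali")),
        App("del", T("gap", EMPTY), NT("ali")),
        ...
    ], choice=True)

Terminal parsers and their yield sizes:

============  =========  ==========================================
terminal      yield      result value
============  =========  ==========================================
``EMPTY``     (0, 0)     nothing
``CHAR``      (1, 1)     the character (any alphabet, incl. floats)
``CHAR(c)``   (1, 1)     the character, required to equal ``c``
``REGION``    (1, inf)   a subword view
``SEQ``       (1, inf)   the integer length of the subword
``VOID``      (0, 0)     nothing (the track is not read)
============  =========  ==========================================

A tuple slot may also name a *single-track nonterminal* (e.g. ``gap = CHAR``)
whose alternatives are bare, possibly filtered, terminals; it parses on that
slot's track only.

Syntactic filters (``minsize``/``maxsize``/``basep``/``banded``) guard a
pattern node: the node is only expanded when the filter accepts the guarded
span(s).  Filters are pure predicates over the inputs and the guarded
per-track spans and are evaluated before the guarded subtree is constructed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .errors import GrammarError
from .signature import ALPHABET, ANSWER, LENGTH, SUBSEQUENCE, VOID, Signature

INF = math.inf


# -- terminals and pattern nodes -------------------------------------------

class Term:
    """A terminal parser. ``CHAR`` may be specialized to one character: ``CHAR('x')``."""

    __slots__ = ("kind", "char")

    def __init__(self, kind: str, char=None):
        self.kind = kind
        self.char = char

    def __call__(self, char) -> "Term":
        if self.kind != "CHAR":
            raise GrammarError(f"only CHAR can be specialized to a character, not {self.kind}")
        return Term("CHAR", char)

    def __repr__(self) -> str:
        if self.kind == "CHAR" and self.char is not None:
            return f"CHAR({self.char!r})"
        return self.kind


EMPTY = Term("EMPTY")
CHAR = Term("CHAR")
REGION = Term("REGION")
SEQ = Term("SEQ")
VOIDT = Term("VOID")

#: terminal kind -> (min yield, max yield)
TERM_YIELD = {
    "EMPTY": (0, 0),
    "VOID": (0, 0),
    "CHAR": (1, 1),
    "REGION": (1, INF),
    "SEQ": (1, INF),
}

#: terminal kind -> the sort it satisfies in a signature tuple slot
TERM_SORT = {
    "EMPTY": VOID,
    "VOID": VOID,
    "CHAR": ALPHABET,
    "REGION": SUBSEQUENCE,
    "SEQ": LENGTH,
}


@dataclass(frozen=True)
class FilterSpec:
    """A named, pure syntactic filter.

    ``fn(inputs, spans, tracks)`` receives the full input tuple, the guarded
    half-open span per covered track, and the covered track indices; it
    returns whether the guarded pattern node may be expanded.
    """

    name: str
    params: tuple
    fn: Callable[[tuple, tuple, tuple], bool]

    def __call__(self, inputs, spans, tracks) -> bool:
        return self.fn(inputs, spans, tracks)

    def __repr__(self) -> str:
        return f"{self.name}({', '.join(map(repr, self.params))})"


class T:
    """A terminal tuple: one slot per covered track.

    Slots are :class:`Term` objects or names of single-track nonterminals.
    """

    __slots__ = ("slots", "filters")

    def __init__(self, *slots: Union[Term, str], filters: Sequence[FilterSpec] = ()):
        if not slots:
            raise GrammarError("terminal tuple needs at least one slot")
        self.slots = slots
        self.filters = tuple(filters)

    def with_filter(self, *fs: FilterSpec) -> "T":
        return T(*self.slots, filters=self.filters + tuple(fs))

    def __repr__(self) -> str:
        return "<" + ", ".join(repr(s) for s in self.slots) + ">"


class NT:
    """Reference to a nonterminal spanning all grammar tracks."""

    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def __repr__(self) -> str:
        return self.name


class App:
    """A tree pattern: a function symbol applied to ordered arguments."""

    __slots__ = ("fname", "args", "filters")

    def __init__(self, fname: str, *args: Union["App", NT, T], filters: Sequence[FilterSpec] = ()):
        self.fname = fname
        self.args = args
        self.filters = tuple(filters)

    def with_filter(self, *fs: FilterSpec) -> "App":
        return App(self.fname, *self.args, filters=self.filters + tuple(fs))

    def __repr__(self) -> str:
        s = f"{self.fname}({', '.join(repr(a) for a in self.args)})"
        for f in self.filters:
            s += f" with {f!r}"
        return s


PatternNode = Union[App, T]


@dataclass
class Nonterminal:
    """A named list of alternatives with an optional choice marker.

    ``choice=True`` corresponds to the ``# h`` marker: the objective function
    is applied to the concatenated answers of the alternatives.  Without it
    the answer list passes through unchanged.
    """

    name: str
    alternatives: List[PatternNode]
    choice: bool = False


class Grammar:
    """Axiom + nonterminals over a signature, for 1 or 2 input tracks."""

    def __init__(
        self,
        name: str,
        signature: Signature,
        axiom: str,
        nonterminals: Iterable[Nonterminal],
    ) -> None:
        self.name = name
        self.signature = signature
        self.axiom = axiom
        self.tracks = signature.tracks
        self.nonterminals: Dict[str, Nonterminal] = {}
        for nt in nonterminals:
            if nt.name in self.nonterminals:
                raise GrammarError(f"duplicate nonterminal {nt.name!r}")
            self.nonterminals[nt.name] = nt
        if axiom not in self.nonterminals:
            raise GrammarError(f"axiom {axiom!r} is not a nonterminal of {name!r}")
        self._coverage: Optional[Dict[str, str]] = None
        self._diagnostics: Optional[List["Diagnostic"]] = None
        self._yields: Optional[Dict[str, "YieldSize"]] = None

    # -- structural helpers -------------------------------------------------
    def coverage(self) -> Dict[str, str]:
        """Per nonterminal: ``"full"`` (all tracks) or ``"slot"`` (one track).

        The axiom and every ``NT()``-referenced nonterminal are full-width;
        nonterminals referenced from terminal-tuple slots are single-track.
        Inconsistent usage is reported by :func:`check_grammar`.
        """
        if self._coverage is not None:
            return self._coverage
        cov: Dict[str, Set[str]] = {n: set() for n in self.nonterminals}
        cov[self.axiom].add("full")

        def walk(node: PatternNode) -> None:
            if isinstance(node, T):
                for s in node.slots:
                    if isinstance(s, str) and s in cov:
                        cov[s].add("slot")
            elif isinstance(node, App):
                for a in node.args:
                    if isinstance(a, NT):
                        if a.name in cov:
                            cov[a.name].add("full")
                    else:
                        walk(a)

        for nt in self.nonterminals.values():
            for alt in nt.alternatives:
                walk(alt)
        self._coverage = {
            n: ("slot" if kinds == {"slot"} else "full") for n, kinds in cov.items()
        }
        return self._coverage

    def diagnostics(self) -> List["Diagnostic"]:
        if self._diagnostics is None:
            self._diagnostics = check_grammar(self)
        return self._diagnostics

    def yields(self) -> Dict[str, "YieldSize"]:
        if self._yields is None:
            self._yields = yield_size_analysis(self)
        return self._yields

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Grammar({self.name!r}, axiom={self.axiom!r}, nts={list(self.nonterminals)})"


# -- diagnostics ------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    level: str  # "fatal" | "warning"
    code: str
    message: str
    location: str = ""

    @property
    def fatal(self) -> bool:
        return self.level == "fatal"


def _references(node: PatternNode):
    """Yield (kind, name) for nonterminal references in a pattern node."""
    if isinstance(node, T):
        for s in node.slots:
            if isinstance(s, str):
                yield ("slot", s)
    else:
        for a in node.args:
            if isinstance(a, NT):
                yield ("full", a.name)
            else:
                yield from _references(a)


def check_grammar(g: Grammar) -> List[Diagnostic]:
    """Validate a grammar; returns diagnostics (fatal ones block solving).

    Checks: unknown function symbols, arity and sort mismatches against the
    signature, dangling nonterminal references, inconsistent track usage,
    unreachable and unproductive nonterminals, and cycles that consume no
    input (epsilon-cycles), which would make the search space infinite.
    """
    diags: List[Diagnostic] = []
    sig = g.signature
    cov = g.coverage()

    def fatal(code: str, msg: str, loc: str = "") -> None:
        diags.append(Diagnostic("fatal", code, msg, loc))

    def warn(code: str, msg: str, loc: str = "") -> None:
        diags.append(Diagnostic("warning", code, msg, loc))

    def check_tuple(node: T, sorts: tuple, loc: str) -> None:
        if len(node.slots) != len(sorts):
            fatal(
                "arity",
                f"terminal tuple has {len(node.slots)} slot(s), declaration "
                f"expects {len(sorts)}",
                loc,
            )
            return
        for k, (slot, sort) in enumerate(zip(node.slots, sorts)):
            if isinstance(slot, str):
                sub = g.nonterminals.get(slot)
                if sub is None:
                    fatal("undefined", f"unknown nonterminal {slot!r} in tuple slot", loc)
                    continue
                for alt in sub.alternatives:
                    if not isinstance(alt, T) or len(alt.slots) != 1 or isinstance(alt.slots[0], str):
                        fatal(
                            "sort",
                            f"nonterminal {slot!r} is used in a tuple slot and must "
                            f"consist of bare single-slot terminals",
                            loc,
                        )
                    elif TERM_SORT[alt.slots[0].kind] != sort:
                        fatal(
                            "sort",
                            f"slot {k}: nonterminal {slot!r} yields sort "
                            f"{TERM_SORT[alt.slots[0].kind]!r}, expected {sort!r}",
                            loc,
                        )
            else:
                if TERM_SORT[slot.kind] != sort:
                    fatal(
                        "sort",
                        f"slot {k}: terminal {slot!r} has sort {TERM_SORT[slot.kind]!r}, "
                        f"expected {sort!r}",
                        loc,
                    )

    def check_app(node: App, loc: str) -> None:
        if node.fname not in sig:
            fatal("undefined", f"unknown function symbol {node.fname!r}", loc)
            return
        decl = sig.function(node.fname)
        if len(node.args) != decl.arity:
            fatal(
                "arity",
                f"{node.fname!r} applied to {len(node.args)} argument(s), "
                f"declared arity is {decl.arity}",
                loc,
            )
            return
        for arg, sort in zip(node.args, decl.args):
            if sort == ANSWER:
                if isinstance(arg, NT):
                    if arg.name not in g.nonterminals:
                        fatal("undefined", f"unknown nonterminal {arg.name!r}", loc)
                elif isinstance(arg, App):
                    check_app(arg, f"{loc} > {arg.fname}")
                else:
                    fatal(
                        "sort",
                        f"{node.fname!r}: answer argument filled by terminal tuple {arg!r}",
                        loc,
                    )
            else:
                if isinstance(arg, T):
                    check_tuple(arg, sort, loc)
                else:
                    fatal(
                        "sort",
                        f"{node.fname!r}: terminal argument filled by {arg!r}",
                        loc,
                    )

    for nt in g.nonterminals.values():
        for idx, alt in enumerate(nt.alternatives):
            loc = f"{nt.name}[{idx}]"
            if isinstance(alt, App):
                check_app(alt, loc)
            elif isinstance(alt, T):
                if cov.get(nt.name) == "full" and g.tracks != len(alt.slots):
                    fatal(
                        "arity",
                        f"bare terminal alternative of {nt.name!r} has "
                        f"{len(alt.slots)} slot(s) for a {g.tracks}-track grammar",
                        loc,
                    )
            else:
                fatal("sort", f"alternative is not a pattern: {alt!r}", loc)

    # reachability from the axiom
    reachable: Set[str] = set()
    stack = [g.axiom]
    while stack:
        n = stack.pop()
        if n in reachable:
            continue
        reachable.add(n)
        for alt in g.nonterminals[n].alternatives:
            for _, ref in _references(alt):
                if ref in g.nonterminals and ref not in reachable:
                    stack.append(ref)
    for n in g.nonterminals:
        if n not in reachable:
            warn("unreachable", f"nonterminal {n!r} is unreachable from the axiom", n)

    # productivity: can the nonterminal derive at least one finite candidate?
    productive: Set[str] = set()
    changed = True
    while changed:
        changed = False

        def prod_node(node: PatternNode) -> bool:
            if isinstance(node, T):
                return all(
                    (not isinstance(s, str)) or s in productive for s in node.slots
                )
            return all(
                (a.name in productive) if isinstance(a, NT) else prod_node(a)
                for a in node.args
            )

        for n, nt in g.nonterminals.items():
            if n not in productive and any(prod_node(a) for a in nt.alternatives):
                productive.add(n)
                changed = True
    for n in g.nonterminals:
        if n not in productive:
            level = "fatal" if n in reachable else "warning"
            diags.append(
                Diagnostic(level, "unproductive", f"nonterminal {n!r} derives no finite candidate", n)
            )

    # epsilon-cycles: a cycle along edges where the rest of the pattern can
    # consume nothing, i.e. the same subproblem could recur forever.
    yields = yield_size_analysis(g, _for_diagnostics=True)

    def node_min(node, track_of_slot=None) -> float:
        # minimum total yield of a pattern node, summed over covered tracks
        if isinstance(node, T):
            total = 0.0
            for s in node.slots:
                if isinstance(s, str):
                    ys = yields.get(s)
                    total += ys.per_track[0][0] if ys else 0
                else:
                    total += TERM_YIELD[s.kind][0]
            return total
        total = 0.0
        for a in node.args:
            if isinstance(a, NT):
                ys = yields.get(a.name)
                total += sum(b[0] for b in ys.per_track) if ys else 0
            else:
                total += node_min(a)
        return total

    eps_edges: Dict[str, Set[str]] = {n: set() for n in g.nonterminals}
    for n, nt in g.nonterminals.items():
        for alt in nt.alternatives:
            alt_min = node_min(alt)
            for kind, ref in _references(alt):
                if ref not in g.nonterminals:
                    continue
                ys = yields.get(ref)
                ref_min = (
                    ys.per_track[0][0]
                    if (ys and kind == "slot")
                    else (sum(b[0] for b in ys.per_track) if ys else 0)
                )
                ref_min = 0 if ref_min == INF else ref_min
                rest = (0 if alt_min == INF else alt_min) - ref_min
                if rest <= 0:
                    eps_edges[n].add(ref)

    # find strongly-connected components with an epsilon edge (incl. self loops)
    def on_eps_cycle(start: str) -> bool:
        seen = set()
        stack = list(eps_edges[start])
        while stack:
            n = stack.pop()
            if n == start:
                return True
            if n in seen:
                continue
            seen.add(n)
            stack.extend(eps_edges[n])
        return False

    for n in g.nonterminals:
        if n in reachable and on_eps_cycle(n):
            fatal(
                "epsilon-cycle",
                f"nonterminal {n!r} can reach itself without consuming input; "
                f"the search space would be infinite",
                n,
            )
    return diags


# -- yield size analysis ----------------------------------------------------

@dataclass(frozen=True)
class YieldSize:
    """Per covered track: (min, max) length of any derivable yield."""

    per_track: Tuple[Tuple[float, float], ...]

    def __repr__(self) -> str:
        return "YieldSize(" + ", ".join(f"({a},{b})" for a, b in self.per_track) + ")"


def _filter_bounds(filters: Sequence[FilterSpec]) -> Tuple[float, float]:
    lo, hi = 0.0, INF
    for f in filters:
        if f.name == "minsize":
            lo = max(lo, f.params[0])
        elif f.name == "maxsize":
            hi = min(hi, f.params[0])
    return lo, hi


def yield_size_analysis(g: Grammar, _for_diagnostics: bool = False) -> Dict[str, YieldSize]:
    """Least-fixpoint per-track yield bounds for every nonterminal.

    Terminals contribute their fixed yields, ``minsize``/``maxsize`` filters
    tighten single-track bounds, alternatives combine elementwise (min of
    mins, max of maxs) and concatenation within a pattern adds.  The engine
    uses these bounds to restrict split-point loops.
    """
    if not _for_diagnostics:
        bad = [d for d in g.diagnostics() if d.fatal]
        if bad:
            raise GrammarError(f"grammar {g.name!r} has fatal diagnostics: {bad[0].message}")
    cov = g.coverage()
    width = {n: (1 if cov[n] == "slot" else g.tracks) for n in g.nonterminals}
    est: Dict[str, List[List[float]]] = {
        n: [[INF, 0.0] for _ in range(width[n])] for n in g.nonterminals
    }

    def node_bounds(node: PatternNode, w: int) -> List[List[float]]:
        if isinstance(node, T):
            out = []
            for s in node.slots:
                if isinstance(s, str):
                    b = est.get(s, [[INF, 0.0]])[0]
                    out.append([b[0], b[1]])
                else:
                    lo, hi = TERM_YIELD[s.kind]
                    out.append([float(lo), float(hi)])
            if len(node.slots) == 1:
                flo, fhi = _filter_bounds(node.filters)
                out[0][0] = max(out[0][0], flo)
                out[0][1] = min(out[0][1], fhi)
            return out
        total = [[0.0, 0.0] for _ in range(w)]
        for a in node.args:
            if isinstance(a, NT):
                sub = est.get(a.name, [[INF, 0.0] for _ in range(w)])
            else:
                sub = node_bounds(a, w)
            for t in range(w):
                total[t][0] += sub[t][0]
                total[t][1] += sub[t][1]
        if w == 1:
            flo, fhi = _filter_bounds(node.filters)
            total[0][0] = max(total[0][0], flo)
            total[0][1] = min(total[0][1], fhi)
        return total

    max_rounds = 4 * len(g.nonterminals) + 8
    for rounds in range(max_rounds + 4):
        changed = False
        for n, nt in g.nonterminals.items():
            w = width[n]
            lo = [INF] * w
            hi = [0.0] * w
            for alt in nt.alternatives:
                b = node_bounds(alt, w)
                for t in range(w):
                    lo[t] = min(lo[t], b[t][0])
                    hi[t] = max(hi[t], b[t][1])
            for t in range(w):
                if rounds >= max_rounds and hi[t] > est[n][t][1]:
                    hi[t] = INF  # still growing: diverges to infinity
                if (lo[t], hi[t]) != tuple(est[n][t]):
                    est[n][t] = [lo[t], hi[t]]
                    changed = True
        if not changed:
            break
    return {
        n: YieldSize(tuple((b[0], b[1]) for b in est[n])) for n in g.nonterminals
    }


# -- table design -----------------------------------------------------------

def table_design(
    g: Grammar, mode: Union[str, Sequence[str]] = "auto"
) -> FrozenSet[str]:
    """Decide which nonterminals to tabulate.

    ``"all"`` tabulates every nonterminal.  ``"auto"`` applies a safe greedy
    heuristic: tabulate a nonterminal if it lies on a cycle of the dependency
    graph, or if it is referenced from more than one pattern position.  A
    user-supplied collection is taken as-is, with a warning (via
    :mod:`warnings`) if a cycle nonterminal is omitted.  With ``auto`` or
    ``all``, every subproblem is evaluated at most once.
    """
    import warnings

    names = set(g.nonterminals)
    if mode == "all":
        return frozenset(names)

    edges: Dict[str, Set[str]] = {n: set() for n in names}
    refcount: Dict[str, int] = {n: 0 for n in names}
    for n, nt in g.nonterminals.items():
        for alt in nt.alternatives:
            for _, ref in _references(alt):
                if ref in names:
                    edges[n].add(ref)
                    refcount[ref] += 1

    def on_cycle(start: str) -> bool:
        seen: Set[str] = set()
        stack = list(edges[start])
        while stack:
            x = stack.pop()
            if x == start:
                return True
            if x in seen:
                continue
            seen.add(x)
            stack.extend(edges[x])
        return False

    cyclic = {n for n in names if on_cycle(n)}
    if mode == "auto":
        return frozenset(cyclic | {n for n in names if refcount[n] > 1})

    user = set(mode)
    unknown = user - names
    if unknown:
        raise GrammarError(f"table design names unknown nonterminal(s) {sorted(unknown)}")
    missed = cyclic - user
    if missed:
        warnings.warn(
            f"table design omits cycle nonterminal(s) {sorted(missed)}; "
            f"evaluation may repeat subproblems",
            stacklevel=2,
        )
    return frozenset(user)


# -- built-in filters -------------------------------------------------------

DEFAULT_PAIRS: FrozenSet[FrozenSet[str]] = frozenset(
    {frozenset("AU"), frozenset("GC"), frozenset("GU")}
)


def minsize(k: int) -> FilterSpec:
    """Accept only spans of length >= k (every covered track)."""
    return FilterSpec(
        "minsize", (k,), lambda inputs, spans, tracks: all(j - i >= k for i, j in spans)
    )


def maxsize(k: int) -> FilterSpec:
    """Accept only spans of length <= k (every covered track)."""
    return FilterSpec(
        "maxsize", (k,), lambda inputs, spans, tracks: all(j - i <= k for i, j in spans)
    )


def basep(pairs: Iterable[Iterable[str]] = DEFAULT_PAIRS) -> FilterSpec:
    """Accept spans whose first and last characters are complementary.

    ``pairs`` is a set of unordered character pairs; the default is the RNA
    pairing set {A-U, G-C, G-U} (wobble included).  Spans shorter than 2
    evaluate to false.
    """
    pairset = frozenset(frozenset(p) for p in pairs)

    def fn(inputs, spans, tracks):
        (i, j) = spans[0]
        if j - i < 2:
            return False
        x = inputs[tracks[0]]
        return frozenset({x[i], x[j - 1]}) in pairset

    return FilterSpec("basep", (pairset,), fn)


def banded(w: int, left_pad: Optional[int] = None, right_pad: Optional[int] = None) -> FilterSpec:
    """Two-track band filter: restrict subproblems to a diagonal band.

    Accepts a subproblem when the left boundaries satisfy ``|i1 - i2| <= w``.
    The optional pads widen the band near the sequence ends: a subproblem is
    also accepted when both left boundaries lie within ``left_pad`` of the
    starts, or within ``right_pad`` of the ends.  Pads default to ``w``.
    With ``w`` at least the input length the filter accepts everything, so
    banded and unbanded solutions coincide.
    """
    lp = w if left_pad is None else left_pad
    rp = w if right_pad is None else right_pad

    def fn(inputs, spans, tracks):
        if len(spans) < 2:
            raise GrammarError("banded requires a two-track subproblem")
        (i1, _), (i2, _) = spans[0], spans[1]
        if abs(i1 - i2) <= w:
            return True
        if i1 <= lp and i2 <= lp:
            return True
        n1 = len(inputs[tracks[0]])
        n2 = len(inputs[tracks[1]])
        return (n1 - i1) <= rp and (n2 - i2) <= rp

    return FilterSpec("banded", (w, lp, rp), fn)


def builtin_filters() -> Dict[str, Callable[..., FilterSpec]]:
    """The built-in syntactic filter constructors."""
    return {"minsize": minsize, "maxsize": maxsize, "basep": basep, "banded": banded}
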