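"""Algebra products: combining two algebras over one signature.

A product takes two algebras ``A`` and ``B`` over the same signature and
yields a combined algebra over pair answers.  The scoring functions always
apply componentwise; the operators differ in their choice function:

``cartesian``     ``A % B``  -- ``h_A`` on first components and ``h_B`` on
                  second components independently (both must be unitary; the
                  two halves of the result may come from different
                  candidates).
``lexicographic`` ``A * B``  -- ``h_A`` picks the surviving first-component
                  classes, then ``h_B`` runs within each class.  With a
                  classifying ``A`` this is classified DP; with an
                  enumerative ``B`` it reports candidates.
``take_one``      ``A . B``  -- lexicographic, but one pair per class
                  (suppressing co-optimals) under the deterministic
                  candidate order.
``interleaved``   ``A / B``  -- per-class selection as lexicographic, then
                  ``h_B`` once more across all surviving classes.
``overlay``       ``A | B``  -- forward evaluation under ``A`` alone; ``B``
                  is materialized only during stochastic backtracing.

Products can be nested, and combined with a user-defined semantic filter via
:func:`suchthat`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Callable, List, Optional, Sequence, Union

from .algebra import (
    Algebra,
    ENUMERATIVE,
    SELECTIVE,
    SET_VALUED,
    SYNOPTIC,
    UNITARY,
)
from .candidates import TerminalLeaf, canonical
from .errors import AlgebraError

AnyAlgebra = Union[Algebra, "ProductAlgebra"]


@dataclass(frozen=True)
class PairAnswer:
    """A combined answer: one component per operand algebra."""

    first: Any
    second: Any

    def __iter__(self):
        yield self.first
        yield self.second

    def __repr__(self) -> str:
        return f"({self.first!r}, {self.second!r})"


def _is_set_like(alg: AnyAlgebra) -> bool:
    # A unitary choice returns a singleton, which is trivially duplicate-free.
    return alg.has(SET_VALUED) or alg.has(ENUMERATIVE) or alg.has(UNITARY)


class ProductAlgebra:
    """A combined algebra over pair answers; use the constructor helpers
    (:func:`lexicographic`, :func:`cartesian`, ...) rather than this class
    directly."""

    OPS = ("cartesian", "lexicographic", "take_one", "interleaved", "overlay")

    def __init__(self, op: str, left: AnyAlgebra, right: AnyAlgebra) -> None:
        if op not in self.OPS:
            raise AlgebraError(f"unknown product operator {op!r}")
        if set(left.signature.functions) != set(right.signature.functions) or (
            left.signature.name != right.signature.name
        ):
            raise AlgebraError(
                f"product operands implement different signatures: "
                f"{left.signature.name!r} vs {right.signature.name!r}"
            )
        self.op = op
        self.left = left
        self.right = right
        self.signature = left.signature
        self._post_filter: Optional[Callable[[Any], bool]] = None
        self.name = f"({left.name} {op} {right.name})"
        self.properties = self._derive_properties()

    def _derive_properties(self) -> frozenset:
        flags = set()
        if self.op == "overlay":
            return frozenset(self.left.properties)
        if self.op == "cartesian":
            flags.add(UNITARY)
        if self.op == "take_one" and self.left.has(UNITARY):
            flags.add(UNITARY)
        if self.left.has(SELECTIVE) and self.right.has(SELECTIVE):
            flags.add(SELECTIVE)
        return frozenset(flags)

    def has(self, flag: str) -> bool:
        return flag in self.properties

    # -- evaluation ---------------------------------------------------------
    def apply(self, fname: str, args: Sequence[Any]):
        if self.op == "overlay":
            return self.left.apply(fname, args)
        la, ra = [], []
        for a in args:
            if isinstance(a, PairAnswer):
                la.append(a.first)
                ra.append(a.second)
            else:  # terminal leaf, shared by both components
                la.append(a)
                ra.append(a)
        return PairAnswer(self.left.apply(fname, la), self.right.apply(fname, ra))

    def choice(self, answers: list) -> list:
        out = getattr(self, f"_choice_{self.op}")(answers)
        if self._post_filter is not None:
            out = [x for x in out if self._post_filter(x)]
        return out

    def choice_fn(self, answers: list) -> list:  # uniform with Algebra
        return self.choice(answers)

    # -- operator choice functions ------------------------------------------
    def _classes(self, answers: List[PairAnswer]):
        """Surviving first components (deduplicated, in h_A order) and the
        per-class second-component groups."""
        firsts = [p.first for p in answers]
        chosen = self.left.choice(firsts)
        seen = set()
        classes = []
        for a in chosen:
            key = canonical(a)
            if key not in seen:
                seen.add(key)
                classes.append((a, key))
        groups = {key: [] for _, key in classes}
        for p in answers:
            key = canonical(p.first)
            if key in groups:
                groups[key].append(p.second)
        return classes, groups

    def _choice_lexicographic(self, answers):
        classes, groups = self._classes(answers)
        out = []
        for a, key in classes:
            for b in self.right.choice(groups[key]):
                out.append(PairAnswer(a, b))
        return out

    def _choice_take_one(self, answers):
        classes, groups = self._classes(answers)
        out = []
        for a, key in classes:
            chosen = self.right.choice(groups[key])
            if chosen:
                out.append(PairAnswer(a, chosen[0]))
        return out

    def _choice_cartesian(self, answers):
        if not answers:
            return []
        fa = self.left.choice([p.first for p in answers])
        fb = self.right.choice([p.second for p in answers])
        if not fa or not fb:
            return []
        return [PairAnswer(fa[0], fb[0])]

    def _choice_interleaved(self, answers):
        survivors = self._choice_lexicographic(answers)
        if not survivors:
            return []
        keep = {canonical(b) for b in self.right.choice([p.second for p in survivors])}
        return [p for p in survivors if canonical(p.second) in keep]

    def _choice_overlay(self, answers):
        return self.left.choice(answers)

    def __repr__(self) -> str:
        return f"ProductAlgebra{self.name}"


# -- constructors with Table-style admissibility checks ----------------------

def lexicographic(A: AnyAlgebra, B: AnyAlgebra) -> ProductAlgebra:
    """Optimization under lexicographic ordering (``A * B``)."""
    if not A.has(SELECTIVE):
        raise AlgebraError("lexicographic product requires a selective first algebra")
    if not _is_set_like(A):
        warnings.warn(
            f"lexicographic product with a non-set-valued first algebra "
            f"{A.name!r}: duplicate classes may repeat work",
            stacklevel=2,
        )
    return ProductAlgebra("lexicographic", A, B)


def cartesian(A: AnyAlgebra, B: AnyAlgebra) -> ProductAlgebra:
    """Cartesian product (``A % B``): independent optima, both unitary."""
    for x, side in ((A, "first"), (B, "second")):
        if not x.has(UNITARY):
            raise AlgebraError(f"cartesian product requires a unitary {side} algebra")
    return ProductAlgebra("cartesian", A, B)


def take_one(A: AnyAlgebra, B: AnyAlgebra, _checked: bool = True) -> ProductAlgebra:
    """Lexicographic product suppressing co-optimals (``A . B``)."""
    if _checked and not (A.has(ENUMERATIVE) or _is_set_like(A)):
        raise AlgebraError(
            "take-one product requires an enumerative or set-valued first algebra"
        )
    return ProductAlgebra("take_one", A, B)


def interleaved(A: AnyAlgebra, B: AnyAlgebra) -> ProductAlgebra:
    """Optimization across classification (``A / B``)."""
    if not (A.has(ENUMERATIVE) or _is_set_like(A)):
        raise AlgebraError(
            "interleaved product requires an enumerative or set-valued first algebra"
        )
    if not B.has(SELECTIVE):
        raise AlgebraError("interleaved product requires a selective second algebra")
    return ProductAlgebra("interleaved", A, B)


def overlay(A: AnyAlgebra, B: AnyAlgebra) -> ProductAlgebra:
    """Stochastic-backtrace overlay (``A | B``).

    Forward evaluation uses ``A`` only; ``B`` is materialized exclusively
    during sampling (:func:`adpkit.engine.sample`).
    """
    if not A.has(SYNOPTIC):
        raise AlgebraError("overlay product requires a synoptic first algebra")
    if not B.has(ENUMERATIVE):
        raise AlgebraError("overlay product requires an enumerative second algebra")
    return ProductAlgebra("overlay", A, B)


def suchthat(P: AnyAlgebra, pred: Callable[[Any], bool]) -> AnyAlgebra:
    """Attach a semantic filter: after every application of the choice
    function at a nonterminal, answers failing ``pred`` are removed.

    The caller is responsible for ``pred`` being pruning-safe: a removed
    answer must not have been extensible to a surviving final answer.  This
    is documented, not checked.
    """
    import copy

    clone = copy.copy(P)
    prev = P._post_filter
    clone._post_filter = (
        pred if prev is None else (lambda x, _p=prev, _q=pred: _p(x) and _q(x))
    )
    clone.name = f"({P.name} suchthat {getattr(pred, '__name__', 'pred')})"
    return clone


# -- product expression parsing ---------------------------------------------

DEFAULT_GLYPHS = {
    "*": lexicographic,
    "%": cartesian,
    ".": take_one,
    "/": interleaved,
    "|": overlay,
}


def parse_product(
    expr: str, algebras: dict, glyphs: Optional[dict] = None
) -> AnyAlgebra:
    """Parse a product expression such as ``"score*print"`` or
    ``"score*(length%mismatch%seqlen)"`` against a name->algebra mapping.

    Operators associate to the left and share one precedence level;
    parentheses group.  The glyph table is configurable.
    """
    ops = glyphs or DEFAULT_GLYPHS
    tokens: List[str] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
        elif c in ops or c in "()":
            tokens.append(c)
            i += 1
        elif c.isalnum() or c == "_":
            j = i
            while j < len(expr) and (expr[j].isalnum() or expr[j] == "_"):
                j += 1
            tokens.append(expr[i:j])
            i = j
        else:
            raise AlgebraError(f"unexpected character {c!r} in product expression")
    pos = 0

    def atom():
        nonlocal pos
        if pos >= len(tokens):
            raise AlgebraError(f"truncated product expression {expr!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            node = expression()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise AlgebraError(f"unbalanced parentheses in {expr!r}")
            pos += 1
            return node
        if tok in ops or tok == ")":
            raise AlgebraError(f"misplaced {tok!r} in product expression {expr!r}")
        pos += 1
        try:
            return algebras[tok]
        except KeyError:
            raise AlgebraError(
                f"unknown algebra {tok!r}; available: {sorted(algebras)}"
            ) from None

    def expression():
        nonlocal pos
        node = atom()
        while pos < len(tokens) and tokens[pos] in ops:
            op = ops[tokens[pos]]
            pos += 1
            node = op(node, atom())
        return node

    node = expression()
    if pos != len(tokens):
        raise AlgebraError(f"trailing tokens in product expression {expr!r}")
    return node
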