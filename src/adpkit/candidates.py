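"""Candidate trees: explicit members of a grammar's search space.

A candidate is a tree whose internal nodes are function symbols of the
signature and whose leaves carry the consumed input: characters, subword
views, parsed lengths, or nothing (for empty/void slots).  Evaluating a
candidate under an algebra applies the algebra's functions bottom-up and
yields the candidate's score; no choice function is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional, Sequence, Tuple, Union

from .errors import EvaluationError
from .signature import ALPHABET, ANSWER, LENGTH, SUBSEQUENCE, VOID

# Terminal kinds appearing at leaves.
K_EMPTY = "EMPTY"
K_CHAR = "CHAR"
K_REGION = "REGION"
K_SEQ = "SEQ"
K_VOID = "VOID"

#: leaf kind -> the terminal sort it satisfies
KIND_SORT = {
    K_EMPTY: VOID,
    K_VOID: VOID,
    K_CHAR: ALPHABET,
    K_REGION: SUBSEQUENCE,
    K_SEQ: LENGTH,
}


class Region:
    """A contiguous view of one input track, ``seq[start:stop]``.

    Compares and iterates by value, so algebras may index it like a list
    (e.g. ``g[0] + g[1] + g[2] + g[3]`` for one flowgram frame).
    """

    __slots__ = ("seq", "start", "stop")

    def __init__(self, seq: Sequence, start: int, stop: int) -> None:
        self.seq = seq
        self.start = start
        self.stop = stop

    def __len__(self) -> int:
        return self.stop - self.start

    def __getitem__(self, i: int):
        if not 0 <= i < len(self):
            raise IndexError(i)
        return self.seq[self.start + i]

    def __iter__(self):
        for i in range(self.start, self.stop):
            yield self.seq[i]

    def values(self) -> tuple:
        return tuple(self)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Region):
            return self.values() == other.values()
        if isinstance(other, (tuple, list, str)):
            return self.values() == tuple(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.values())

    def __repr__(self) -> str:
        return f"Region({self.values()!r} @ [{self.start},{self.stop}))"


@dataclass(frozen=True)
class SlotValue:
    """The consumed input of one tuple slot at a leaf.

    ``kind`` is one of EMPTY/CHAR/REGION/SEQ/VOID; ``span`` is the half-open
    subword consumed on ``track``; ``value`` is the character (CHAR), the
    :class:`Region` view (REGION), the integer length (SEQ), or ``None``.
    """

    kind: str
    track: int
    span: Tuple[int, int]
    value: Any = None

    def __post_init__(self) -> None:
        i, j = self.span
        if not 0 <= i <= j:
            raise EvaluationError(f"invalid leaf span {self.span}")


@dataclass(frozen=True)
class TerminalLeaf:
    """A leaf of a candidate tree: one :class:`SlotValue` per covered track."""

    slots: Tuple[SlotValue, ...]


class CandidateTree:
    """Internal node of a candidate: a function symbol over sub-candidates.

    ``children`` are :class:`CandidateTree` or :class:`TerminalLeaf` objects
    in the declared argument order.
    """

    __slots__ = ("node", "children", "_canon")

    def __init__(
        self, node: str, children: Sequence[Union["CandidateTree", TerminalLeaf]] = ()
    ) -> None:
        self.node = node
        self.children = tuple(children)
        self._canon: Optional[tuple] = None

    def canon(self) -> tuple:
        """A hashable canonical form (used as class key in classified DP)."""
        if self._canon is None:
            self._canon = ("app", self.node, tuple(canonical(c) for c in self.children))
        return self._canon

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CandidateTree) and self.canon() == other.canon()

    def __hash__(self) -> int:
        return hash(self.canon())

    def __repr__(self) -> str:
        parts = []
        for c in self.children:
            if isinstance(c, TerminalLeaf):
                vals = [s.value for s in c.slots if s.kind not in (K_EMPTY, K_VOID)]
                parts.append("<" + ",".join(repr(v) for v in vals) + ">")
            else:
                parts.append(repr(c))
        return f"{self.node}({', '.join(parts)})"

    def yields(self, tracks: int) -> Tuple[Tuple[int, int], ...]:
        """Per-track (min position, max position) span covered by the leaves."""
        lo = [None] * tracks
        hi = [None] * tracks

        def visit(n) -> None:
            if isinstance(n, TerminalLeaf):
                for s in n.slots:
                    i, j = s.span
                    if lo[s.track] is None or i < lo[s.track]:
                        lo[s.track] = i
                    if hi[s.track] is None or j > hi[s.track]:
                        hi[s.track] = j
            else:
                for c in n.children:
                    visit(c)

        visit(self)
        return tuple(
            (0, 0) if lo[t] is None else (lo[t], hi[t]) for t in range(tracks)
        )


def canonical(value: Any) -> Any:
    """A hashable, tolerance-aware canonical form of an answer value.

    Floats are rounded to 9 decimals so that co-optimal detection on float
    scores is stable against summation-order noise; containers and candidate
    trees are canonicalized recursively.
    """
    if isinstance(value, float):
        return round(value, 9)
    if isinstance(value, CandidateTree):
        return value.canon()
    if isinstance(value, TerminalLeaf):
        return ("leaf", tuple(canonical(s) for s in value.slots))
    if isinstance(value, SlotValue):
        return (value.kind, value.track, value.span, canonical(value.value))
    if isinstance(value, Region):
        return ("region", tuple(canonical(v) for v in value.values()))
    if isinstance(value, (tuple, list)):
        return tuple(canonical(v) for v in value)
    if hasattr(value, "first") and hasattr(value, "second"):
        return ("pair", canonical(value.first), canonical(value.second))
    return value


def evaluate_candidate(tree: Union[CandidateTree, TerminalLeaf], algebra) -> Any:
    """Evaluate a candidate tree bottom-up under ``algebra``.

    The tree must be well-sorted against ``algebra.signature``: every node's
    function symbol must be declared, with matching arity, answer arguments
    filled by subtrees and terminal-tuple arguments filled by leaves whose
    slot kinds satisfy the declared sorts.  The choice function is *not*
    applied — this is the score of one candidate.
    """
    sig = algebra.signature
    if isinstance(tree, TerminalLeaf):
        raise EvaluationError("a bare terminal leaf is not a candidate")

    def check_leaf(leaf: TerminalLeaf, sorts: tuple, where: str) -> None:
        if len(leaf.slots) != len(sorts):
            raise EvaluationError(
                f"node {where!r}: leaf has {len(leaf.slots)} slot(s), "
                f"declaration expects {len(sorts)}"
            )
        for slot, sort in zip(leaf.slots, sorts):
            if KIND_SORT[slot.kind] != sort:
                raise EvaluationError(
                    f"node {where!r}: slot kind {slot.kind} does not satisfy "
                    f"sort {sort!r}"
                )

    def ev(node):
        decl = sig.function(node.node)
        if len(node.children) != decl.arity:
            raise EvaluationError(
                f"node {node.node!r}: {len(node.children)} argument(s), "
                f"declared arity {decl.arity}"
            )
        args = []
        for child, sort in zip(node.children, decl.args):
            if sort == ANSWER:
                if isinstance(child, TerminalLeaf):
                    raise EvaluationError(
                        f"node {node.node!r}: answer argument filled by a leaf"
                    )
                args.append(ev(child))
            else:
                if not isinstance(child, TerminalLeaf):
                    raise EvaluationError(
                        f"node {node.node!r}: terminal argument filled by a subtree"
                    )
                check_leaf(child, sort, node.node)
                args.append(child)
        return algebra.apply(node.node, args)

    return ev(tree)
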