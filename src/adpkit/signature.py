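"""Signatures: the shared contract between tree grammars and evaluation algebras.

A signature declares a set of named function symbols, each with a list of
argument sorts, plus one choice (objective) symbol.  Both evaluation algebras
and tree grammars are written against a signature: the algebra provides
implementations for every function symbol, the grammar uses them as labels of
its tree patterns.  Argument sorts distinguish

* ``answer``      -- the result of evaluating a subtree,
* ``alphabet``    -- one input character (one flow value, for flowgrams),
* ``subsequence`` -- a contiguous subword view (the REGION terminal),
* ``length``      -- the integer length of a parsed subword (the SEQ terminal),
* ``void``        -- a tuple slot that consumes nothing on its track.

In multi-track signatures the terminal arguments are fixed-width tuples with
one sort per track; a ``void`` slot marks tracks a function does not read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple, Union

from .errors import SignatureError

ALPHABET = "alphabet"
ANSWER = "answer"
SUBSEQUENCE = "subsequence"
LENGTH = "length"
VOID = "void"

TERMINAL_SORTS = frozenset({ALPHABET, SUBSEQUENCE, LENGTH, VOID})

#: An argument sort: the answer sort, or a per-track tuple of terminal sorts.
ArgSort = Union[str, Tuple[str, ...]]


@dataclass(frozen=True)
class FunctionDecl:
    """Declaration of one function symbol of a signature.

    ``args`` holds one entry per argument: the string ``"answer"`` for
    answer-sorted arguments, or a tuple of per-track terminal sorts for
    terminal arguments (1-tuples in single-track signatures).
    """

    name: str
    args: Tuple[ArgSort, ...]
    result: str = ANSWER

    def __post_init__(self) -> None:
        for a in self.args:
            if a == ANSWER:
                continue
            if not isinstance(a, tuple) or not a:
                raise SignatureError(
                    f"{self.name}: argument sort must be 'answer' or a "
                    f"per-track tuple of terminal sorts, got {a!r}"
                )
            for s in a:
                if s not in TERMINAL_SORTS:
                    raise SignatureError(
                        f"{self.name}: unknown terminal sort {s!r} "
                        f"(expected one of {sorted(TERMINAL_SORTS)})"
                    )
        if self.result != ANSWER:
            raise SignatureError(f"{self.name}: result sort must be 'answer'")

    @property
    def arity(self) -> int:
        return len(self.args)


class Signature:
    """A named set of function declarations plus one choice symbol.

    Parameters
    ----------
    name:
        Identifier of the signature (e.g. ``"Align"``).
    tracks:
        Number of input tracks (1 for single sequences, 2 for alignments).
        All terminal argument tuples must have exactly this width.
    functions:
        The function declarations.  Names must be unique.
    choice_name:
        Name of the objective-function symbol (conventionally ``h``); its
        domain and codomain are lists of answers.
    """

    def __init__(
        self,
        name: str,
        tracks: int,
        functions: Iterable[FunctionDecl],
        choice_name: str = "h",
    ) -> None:
        if tracks < 1:
            raise SignatureError("a signature needs at least one track")
        self.name = name
        self.tracks = tracks
        self.choice_name = choice_name
        self.functions: dict[str, FunctionDecl] = {}
        for decl in functions:
            if decl.name in self.functions:
                raise SignatureError(f"duplicate function symbol {decl.name!r}")
            if decl.name == choice_name:
                raise SignatureError(
                    f"function symbol {decl.name!r} collides with the choice symbol"
                )
            for a in decl.args:
                if isinstance(a, tuple) and len(a) != tracks:
                    raise SignatureError(
                        f"{decl.name}: terminal tuple {a!r} has width {len(a)}, "
                        f"signature has {tracks} track(s)"
                    )
            self.functions[decl.name] = decl

    def function(self, name: str) -> FunctionDecl:
        try:
            return self.functions[name]
        except KeyError:
            raise SignatureError(
                f"signature {self.name!r} declares no function {name!r}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.functions

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Signature({self.name!r}, tracks={self.tracks}, functions={list(self.functions)})"
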