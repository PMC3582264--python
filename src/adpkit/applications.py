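"""The shipped application instances: pairwise alignment, Nussinov-style
RNA folding, and banded flowgram alignment.

Each application bundles a signature, a grammar, a dictionary of named
algebras and a dictionary of named instances (product expressions resolved
against those algebras).  The bundles are plain data: everything can be
rebuilt, extended or recombined through the library API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, Optional, Tuple, Union

from .algebra import (
    Algebra,
    ENUMERATIVE,
    SELECTIVE,
    SET_VALUED,
    UNITARY,
    make_count_algebra,
    make_enum_algebra,
)
from .errors import AlgebraError
from .grammar import (
    App,
    CHAR,
    DEFAULT_PAIRS,
    EMPTY,
    Grammar,
    NT,
    Nonterminal,
    REGION,
    SEQ,
    T,
    banded,
    basep,
    maxsize,
    minsize,
)
from .products import AnyAlgebra, parse_product
from .signature import ANSWER, FunctionDecl, Signature


@dataclass
class AppBundle:
    """A configured application: signature, grammar, algebras, instances."""

    name: str
    signature: Signature
    grammar: Grammar
    algebras: Dict[str, Algebra]
    instances: Dict[str, str] = field(default_factory=dict)

    def instance(self, name_or_expr: str) -> AnyAlgebra:
        """Resolve a named instance or an inline product expression."""
        expr = self.instances.get(name_or_expr, name_or_expr)
        if expr in self.algebras:
            return self.algebras[expr]
        return parse_product(expr, self.algebras)


# -- pairwise sequence alignment -------------------------------------------

def alignment_app() -> AppBundle:
    """Global pairwise alignment (Needleman–Wunsch search space).

    Signature ``Align`` with edit operations ``rep``/``del``/``ins`` and the
    empty alignment ``nil``.  Algebras:

    * ``unit``  -- unit edit costs (equal-character rep 0, otherwise 1;
      gaps 1); minimization.  This is Levenshtein distance.
    * ``score`` -- mismatches cost 3, gaps cost 4; minimization.
    * ``print`` -- the alignment itself: both sequences padded with ``-``.
    * ``count`` / ``enum`` -- generated counting / enumeration algebras.

    The named instance ``main = score * print`` reports the optimal score
    with its co-optimal alignments.
    """
    sig = Signature(
        "Align",
        tracks=2,
        functions=[
            FunctionDecl("rep", (("alphabet", "alphabet"), ANSWER)),
            FunctionDecl("del", (("alphabet", "void"), ANSWER)),
            FunctionDecl("ins", (("void", "alphabet"), ANSWER)),
            FunctionDecl("nil", (("void", "void"),)),
        ],
    )
    grammar = Grammar(
        "alignment",
        sig,
        axiom="ali",
        nonterminals=[
            Nonterminal(
                "ali",
                [
                    App("rep", T(CHAR, CHAR), NT("ali")),
                    App("del", T("gap", EMPTY), NT("ali")),
                    App("ins", T(EMPTY, "gap"), NT("ali")),
                    App("nil", T(EMPTY, EMPTY)),
                ],
                choice=True,
            ),
            Nonterminal("gap", [T(CHAR)]),
        ],
    )
    unit = Algebra(
        sig,
        impls={
            "rep": lambda a, b, m: m + (0 if a == b else 1),
            "del": lambda g, m: m + 1,
            "ins": lambda g, m: m + 1,
            "nil": lambda: 0,
        },
        choice=lambda l: [min(l)] if l else [],
        properties={UNITARY, SELECTIVE},
        name="unit",
        answer_type=int,
    )
    score = Algebra(
        sig,
        impls={
            "rep": lambda a, b, m: m + (0 if a == b else 3),
            "del": lambda g, m: m + 4,
            "ins": lambda g, m: m + 4,
            "nil": lambda: 0,
        },
        choice=lambda l: [min(l)] if l else [],
        properties={UNITARY, SELECTIVE},
        name="score",
        answer_type=int,
    )
    pretty = Algebra(
        sig,
        impls={
            "rep": lambda a, b, m: (a + m[0], b + m[1]),
            "del": lambda g, m: (g + m[0], "-" + m[1]),
            "ins": lambda g, m: ("-" + m[0], g + m[1]),
            "nil": lambda: ("", ""),
        },
        choice=lambda l: l,
        properties={ENUMERATIVE, SELECTIVE},
        name="print",
        answer_type=tuple,
    )
    algebras = {
        "unit": unit,
        "score": score,
        "print": pretty,
        "count": make_count_algebra(sig),
        "enum": make_enum_algebra(sig),
    }
    return AppBundle(
        "alignment",
        sig,
        grammar,
        algebras,
        instances={"main": "score*print"},
    )


# -- Nussinov-style RNA folding --------------------------------------------

def nussinov_app(pairs: Iterable[Iterable[str]] = DEFAULT_PAIRS) -> AppBundle:
    """Base-pair maximization over non-crossing RNA secondary structures.

    Grammar ``RNAStruct`` (axiom ``N``) with the three cases: empty
    structure, unpaired first base, and a first base paired with a
    complementary partner (guarded by the ``basep`` filter) followed by the
    rest of the structure.  The split/pair shape gives every structure a
    unique derivation.  Algebras:

    * ``bpmax``     -- +1 per base pair, maximization.
    * ``print``     -- dot-bracket rendering.
    * ``pairclass`` -- the number of pairs as a classification attribute
      (choice keeps all distinct values), for classified DP.
    * ``count`` / ``enum`` -- generated algebras.

    Instances: ``cooptnum = bpmax * count`` (optimum and how many structures
    achieve it), ``cooptimals = bpmax * print`` (all co-optimal structures),
    ``census = pairclass * count`` (structure counts per pair number).
    """
    sig = Signature(
        "Nuss",
        tracks=1,
        functions=[
            FunctionDecl("split", (ANSWER, ANSWER)),
            FunctionDecl("pair", (("alphabet",), ANSWER, ("alphabet",))),
            FunctionDecl("open", (("alphabet",), ANSWER)),
            FunctionDecl("nil", (("void",),)),
        ],
    )
    grammar = Grammar(
        "RNAStruct",
        sig,
        axiom="N",
        nonterminals=[
            Nonterminal(
                "N",
                [
                    App("nil", T(EMPTY)),
                    App("open", T(CHAR), NT("N")),
                    App(
                        "split",
                        App("pair", T(CHAR), NT("N"), T(CHAR), filters=(basep(pairs),)),
                        NT("N"),
                    ),
                ],
                choice=True,
            ),
        ],
    )
    bpmax = Algebra(
        sig,
        impls={
            "split": lambda x, y: x + y,
            "pair": lambda a, x, b: x + 1,
            "open": lambda a, x: x,
            "nil": lambda: 0,
        },
        choice=lambda l: [max(l)] if l else [],
        properties={UNITARY, SELECTIVE},
        name="bpmax",
        answer_type=int,
    )
    dotbracket = Algebra(
        sig,
        impls={
            "split": lambda x, y: x + y,
            "pair": lambda a, x, b: "(" + x + ")",
            "open": lambda a, x: "." + x,
            "nil": lambda: "",
        },
        choice=lambda l: l,
        properties={ENUMERATIVE, SELECTIVE},
        name="print",
        answer_type=str,
    )
    pairclass = bpmax.replace(
        name="pairclass",
        properties={SET_VALUED, SELECTIVE},
        choice_fn=lambda l: list(dict.fromkeys(l)),
    )
    algebras = {
        "bpmax": bpmax,
        "print": dotbracket,
        "pairclass": pairclass,
        "count": make_count_algebra(sig),
        "enum": make_enum_algebra(sig),
    }
    return AppBundle(
        "nussinov",
        sig,
        grammar,
        algebras,
        instances={
            "cooptnum": "bpmax*count",
            "cooptimals": "bpmax*print",
            "census": "pairclass*count",
        },
    )


# -- banded flowgram alignment ----------------------------------------------

def iround(x: float) -> int:
    """Round half away from zero (flow values are non-negative, so this is
    ordinary nearest-integer rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def default_score_table(a: float, b: float) -> float:
    """Replace score for two flow values: ``|round(a) - round(b)| * 7.5``.

    The production mismatch table is external to this package; any total
    symmetric function of two flow values may be injected instead (see
    :func:`adpkit.io.read_score_table`).
    """
    return abs(iround(a) - iround(b)) * 7.5


GAP_OPEN = 15.0 * 4.0  # cost of inserting/deleting one whole frame


def flowgram_app(
    score_table: Optional[Callable[[float, float], float]] = None,
    band: Optional[Union[int, Tuple[int, int, int]]] = None,
) -> AppBundle:
    """Pairwise alignment of pyrosequencing flowgrams.

    A flowgram is a sequence of frames of four flow values; the grammar
    extends the alignment grammar with terminal insertion/deletion symbols
    ``ti``/``td`` (scored zero: flowgrams may differ in length, and only a
    gap at one end is plausible) and restricts ``del``/``ins`` gaps to whole
    frames via ``REGION with minsize(4) with maxsize(4)``.  With ``band``
    given, all alternatives are guarded by the ``banded`` filter; pass an
    ``int`` half-width or a ``(w, left_pad, right_pad)`` triple.

    Algebras (all minimizing):

    * ``score``    -- rep adds ``score_table(a, b)``, frame gaps add 60.0
      (= 15.0 * 4.0), ``nil``/``ti``/``td`` are free.
    * ``mismatch`` -- rep adds ``|round(a) - round(b)|``; gaps add the
      summed rounded flow values of the skipped frame.
    * ``seqlen``   -- like mismatch, but rep adds ``max(round(a), round(b))``.
    * ``length``   -- alignment columns (rep/del/ins add 1), terminal gaps
      excluded.

    Instance ``RKdenoiser = score * (length % mismatch % seqlen)``: optimize
    with score; ride the three auxiliary statistics along the optimum.
    """
    table = score_table or default_score_table
    sig = Signature(
        "FlowAlign",
        tracks=2,
        functions=[
            FunctionDecl("rep", (("alphabet", "alphabet"), ANSWER)),
            FunctionDecl("del", (("subsequence", "void"), ANSWER)),
            FunctionDecl("ins", (("void", "subsequence"), ANSWER)),
            FunctionDecl("nil", (("void", "void"),)),
            FunctionDecl("ti", (("void", "length"),)),
            FunctionDecl("td", (("length", "void"),)),
        ],
    )
    if band is None:
        guards: tuple = ()
    elif isinstance(band, int):
        guards = (banded(band),)
    else:
        guards = (banded(*band),)
    alts = [
        App("rep", T(CHAR, CHAR), NT("ali")),
        App("del", T("gap", EMPTY), NT("ali")),
        App("ins", T(EMPTY, "gap"), NT("ali")),
        App("nil", T(EMPTY, EMPTY)),
        App("ti", T(EMPTY, SEQ)),
        App("td", T(SEQ, EMPTY)),
    ]
    # a filter on a braced group of alternatives distributes over each one
    alts = [a.with_filter(*guards) for a in alts]
    grammar = Grammar(
        "flow",
        sig,
        axiom="ali",
        nonterminals=[
            Nonterminal("ali", alts, choice=True),
            Nonterminal("gap", [T(REGION, filters=(minsize(4), maxsize(4)))]),
        ],
    )

    def minlist(l):
        return [min(l)] if l else []

    def frame_sum(g) -> int:
        return iround(g[0]) + iround(g[1]) + iround(g[2]) + iround(g[3])

    score = Algebra(
        sig,
        impls={
            "rep": lambda a, b, m: m + table(a, b),
            "del": lambda g, m: m + GAP_OPEN,
            "ins": lambda g, m: m + GAP_OPEN,
            "nil": lambda: 0.0,
            "ti": lambda b: 0.0,
            "td": lambda a: 0.0,
        },
        choice=minlist,
        properties={UNITARY, SELECTIVE},
        name="score",
        answer_type=float,
    )
    mismatch = Algebra(
        sig,
        impls={
            "rep": lambda a, b, m: m + abs(iround(a) - iround(b)),
            "del": lambda g, m: m + frame_sum(g),
            "ins": lambda g, m: m + frame_sum(g),
            "nil": lambda: 0,
            "ti": lambda b: 0,
            "td": lambda a: 0,
        },
        choice=minlist,
        properties={UNITARY, SELECTIVE},
        name="mismatch",
        answer_type=int,
    )
    # seqlen extends mismatch: only the replace case differs
    seqlen = mismatch.replace(name="seqlen")
    seqlen.impls = dict(mismatch.impls)
    seqlen.impls["rep"] = lambda a, b, m: m + max(iround(a), iround(b))
    length = Algebra(
        sig,
        impls={
            "rep": lambda a, b, m: m + 1,
            "del": lambda g, m: m + 1,
            "ins": lambda g, m: m + 1,
            "nil": lambda: 0,
            "ti": lambda b: 0,
            "td": lambda a: 0,
        },
        choice=minlist,
        properties={UNITARY, SELECTIVE},
        name="length",
        answer_type=int,
    )
    algebras = {
        "score": score,
        "mismatch": mismatch,
        "seqlen": seqlen,
        "length": length,
        "count": make_count_algebra(sig),
        "enum": make_enum_algebra(sig),
    }
    return AppBundle(
        "flowgram",
        sig,
        grammar,
        algebras,
        instances={"RKdenoiser": "score*(length%mismatch%seqlen)"},
    )


def relative_scores(pair) -> Tuple[float, float]:
    """Convenience post-processing for the denoising instance: the two
    relative scores (score per alignment column, mismatch per aligned
    length) formed downstream of the alignment.  This ratio definition is an
    interpretation; the alignment itself reports the four raw components.
    """
    score = pair.first
    aux = pair.second  # ((length, mismatch), seqlen)
    (length_, mismatch_), seqlen_ = aux.first, aux.second
    rel_score = score / length_ if length_ else 0.0
    rel_mismatch = mismatch_ / seqlen_ if seqlen_ else 0.0
    return rel_score, rel_mismatch
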