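"""Evaluation algebras: scoring functions plus an objective (choice) function.

An algebra binds every function symbol of a signature to an executable
implementation and supplies a choice function that consumes and produces
*lists* of answers.  Property flags describe how the choice behaves:

* ``unitary``     -- choice returns a single answer (min, max, count, ...),
* ``set_valued``  -- choice never returns duplicate answers (k-best, ...),
* ``selective``   -- choice returns a sub-multiset of its input,
* ``enumerative`` -- choice is the identity,
* ``synoptic``    -- choice computes values not attached to any single
  candidate (count, summation); declared, not sample-checkable.

These flags govern which algebra products are admissible (see
:mod:`adpkit.products`).
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, Iterable, List, Optional, Sequence

from .candidates import CandidateTree, TerminalLeaf, K_EMPTY, K_VOID, canonical
from .errors import AlgebraError
from .signature import ANSWER, Signature

UNITARY = "unitary"
SET_VALUED = "set_valued"
SELECTIVE = "selective"
ENUMERATIVE = "enumerative"
SYNOPTIC = "synoptic"

PROPERTY_FLAGS = frozenset({UNITARY, SET_VALUED, SELECTIVE, ENUMERATIVE, SYNOPTIC})


def _flatten(args: Sequence[Any]) -> List[Any]:
    """Flatten structured arguments into the user calling convention.

    Terminal leaves contribute one value per non-void slot, in track order;
    answer arguments pass through.  This mirrors how scoring functions are
    written on paper: ``rep(a, b, m)`` for a two-track character tuple plus
    one answer argument.
    """
    flat: List[Any] = []
    for a in args:
        if isinstance(a, TerminalLeaf):
            for slot in a.slots:
                if slot.kind not in (K_EMPTY, K_VOID):
                    flat.append(slot.value)
        else:
            flat.append(a)
    return flat


class Algebra:
    """Concrete interpretation of a signature.

    Parameters
    ----------
    signature:
        The signature implemented.
    impls:
        Mapping from function name to an executable implementation.  Must
        cover every declared function.  By default implementations receive
        *flattened* arguments (non-void terminal values and answers in
        declared order); with ``structured=True`` they receive the raw
        argument list (answers and :class:`TerminalLeaf` objects).
    choice:
        The objective function, list of answers -> list of answers.
    properties:
        Declared property flags (subset of :data:`PROPERTY_FLAGS`).
    """

    def __init__(
        self,
        signature: Signature,
        impls: Dict[str, Callable],
        choice: Callable[[list], list],
        properties: Iterable[str] = (),
        name: str = "algebra",
        answer_type: Optional[type] = None,
        alphabet_type: Optional[type] = None,
        structured: bool = False,
    ) -> None:
        self.signature = signature
        self.name = name
        self.answer_type = answer_type
        self.alphabet_type = alphabet_type
        self.structured = structured
        self.properties = frozenset(properties)
        unknown = self.properties - PROPERTY_FLAGS
        if unknown:
            raise AlgebraError(f"{name}: unknown property flag(s) {sorted(unknown)}")
        missing = set(signature.functions) - set(impls)
        if missing:
            raise AlgebraError(
                f"{name}: missing implementation(s) for {sorted(missing)} "
                f"of signature {signature.name!r}"
            )
        extra = set(impls) - set(signature.functions)
        if extra:
            raise AlgebraError(
                f"{name}: implementation(s) {sorted(extra)} not declared in "
                f"signature {signature.name!r}"
            )
        self.impls = dict(impls)
        self.choice_fn = choice
        self._post_filter: Optional[Callable[[Any], bool]] = None

    # -- evaluation ---------------------------------------------------------
    def apply(self, fname: str, args: Sequence[Any]) -> Any:
        """Apply the implementation of ``fname`` to structured arguments."""
        impl = self.impls[fname]
        if self.structured:
            return impl(*args)
        return impl(*_flatten(args))

    def choice(self, answers: list) -> list:
        """Apply the objective function (and any ``suchthat`` filter)."""
        out = self.choice_fn(answers)
        if self._post_filter is not None:
            out = [x for x in out if self._post_filter(x)]
        return out

    def has(self, flag: str) -> bool:
        return flag in self.properties

    def replace(self, **overrides) -> "Algebra":
        """A shallow copy with some attributes replaced (impls are shared)."""
        clone = copy.copy(self)
        for k, v in overrides.items():
            if k == "properties":
                v = frozenset(v)
            setattr(clone, k, v)
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Algebra({self.name!r} : {self.signature.name})"


# -- generated algebras -----------------------------------------------------

def make_count_algebra(sig: Signature) -> Algebra:
    """The counting algebra: every candidate counts once.

    Each function returns the product of its answer-typed arguments
    (terminal values contribute factor 1; with no answer arguments the
    result is 1), and the choice function sums the list, returned as a
    singleton.  Solving a grammar with this algebra yields the size of the
    search space.
    """
    impls: Dict[str, Callable] = {}
    for decl in sig.functions.values():
        answer_ix = [i for i, a in enumerate(decl.args) if a == ANSWER]

        def impl(*args, _ix=tuple(answer_ix)):
            out = 1
            for i in _ix:
                out *= args[i]
            return out

        impls[decl.name] = impl

    return Algebra(
        sig,
        impls,
        choice=lambda l: [sum(l)] if l else [],
        properties={UNITARY, SYNOPTIC},
        name="count",
        answer_type=int,
        structured=True,
    )


def make_enum_algebra(sig: Signature) -> Algebra:
    """The enumeration algebra: candidates evaluate to themselves.

    Functions build :class:`CandidateTree` nodes and the choice function is
    the identity, so solving a grammar with this algebra materializes the
    whole search space.
    """
    impls = {
        name: (lambda *args, _n=name: CandidateTree(_n, args))
        for name in sig.functions
    }
    return Algebra(
        sig,
        impls,
        choice=lambda l: l,
        properties={ENUMERATIVE, SELECTIVE},
        name="enum",
        answer_type=CandidateTree,
        structured=True,
    )


# -- dynamic property verification -----------------------------------------

@dataclass
class PropertyCheck:
    flag: str
    status: str  # "pass" | "fail" | "declared-only"
    counterexample: Optional[tuple] = None  # (input list, choice output)


@dataclass
class PropertyReport:
    algebra: str
    checks: List[PropertyCheck] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.status != "fail" for c in self.checks)

    def failures(self) -> List[PropertyCheck]:
        return [c for c in self.checks if c.status == "fail"]


def verify_algebra_properties(
    algebra: Algebra, sample_lists: Sequence[list]
) -> PropertyReport:
    """Check each declared property flag on sample answer lists.

    ``unitary``: the choice result is a singleton; ``set_valued``: no
    duplicates; ``selective``: a sub-multiset of the input; ``enumerative``:
    the input itself.  ``synoptic`` cannot be decided from samples and is
    reported as declared-only.  Failures carry the first counterexample.
    """
    if not sample_lists:
        raise AlgebraError("verify_algebra_properties needs at least one sample list")
    report = PropertyReport(algebra.name)
    for flag in sorted(algebra.properties):
        if flag == SYNOPTIC:
            report.checks.append(PropertyCheck(flag, "declared-only"))
            continue
        bad = None
        for sample in sample_lists:
            out = algebra.choice(list(sample))
            ok = True
            if flag == UNITARY:
                ok = len(out) == 1
            elif flag == SET_VALUED:
                keys = [canonical(x) for x in out]
                ok = len(keys) == len(set(keys))
            elif flag == SELECTIVE:
                have = Counter(canonical(x) for x in sample)
                want = Counter(canonical(x) for x in out)
                ok = all(have[k] >= v for k, v in want.items())
            elif flag == ENUMERATIVE:
                ok = [canonical(x) for x in out] == [canonical(x) for x in sample]
            if not ok:
                bad = (list(sample), out)
                break
        report.checks.append(
            PropertyCheck(flag, "pass" if bad is None else "fail", bad)
        )
    return report
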