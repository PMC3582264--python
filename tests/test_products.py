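"""Algebra products: operator semantics, admissibility, suchthat, parsing."""

import pytest

from adpkit import (
    PairAnswer,
    cartesian,
    interleaved,
    lexicographic,
    overlay,
    parse_product,
    solve,
    suchthat,
    take_one,
)
from adpkit.algebra import Algebra, SELECTIVE, SET_VALUED, UNITARY
from adpkit.errors import AlgebraError
from .conftest import all_strings


def test_lexicographic_reports_cooptimal_census(nus):
    assert solve(nus.grammar, nus.instance("cooptnum"), "GCGC") == [PairAnswer(2, 2)]


def test_classified_dp_groups_structures_by_pair_count(nus):
    got = solve(nus.grammar, nus.instance("census"), "GCGC")
    assert got == [PairAnswer(0, 1), PairAnswer(1, 4), PairAnswer(2, 2)]


def test_product_choice_on_singleton_is_identity(nus):
    prod = nus.instance("cooptnum")
    assert prod.choice([PairAnswer(1, 5)]) == [PairAnswer(1, 5)]


def test_cartesian_optimizes_components_independently(ali):
    prod = cartesian(ali.algebras["unit"], ali.algebras["score"])
    assert solve(ali.grammar, prod, ("A", "C")) == [PairAnswer(1, 3)]


def test_cartesian_of_algebra_with_itself_has_equal_components(ali):
    prod = cartesian(ali.algebras["score"], ali.algebras["score"])
    for x in ("ACA", "C"):
        (pair,) = solve(ali.grammar, prod, (x, "CA"))
        assert pair.first == pair.second


def test_cartesian_requires_unitary_operands(ali):
    with pytest.raises(AlgebraError, match="unitary"):
        cartesian(ali.algebras["enum"], ali.algebras["score"])


def test_take_one_suppresses_cooptimals_deterministically(nus):
    prod = take_one(nus.algebras["bpmax"], nus.algebras["print"])
    assert solve(nus.grammar, prod, "GCGC") == [PairAnswer(2, "()()")]
    assert solve(nus.grammar, prod, "GC") == [PairAnswer(1, "()")]


def test_take_one_equals_lexicographic_on_unique_optimum(nus):
    lex = lexicographic(nus.algebras["bpmax"], nus.algebras["print"])
    one = take_one(nus.algebras["bpmax"], nus.algebras["print"])
    for x in all_strings("GCA", 4):
        l = solve(nus.grammar, lex, x)
        t = solve(nus.grammar, one, x)
        assert t[0] == l[0]  # take-one keeps the first co-optimal
        assert len(t) == 1
        if len(l) == 1:
            assert t == l


def test_interleaved_keeps_globally_best_class(nus):
    maxint = Algebra(
        nus.signature,
        impls=nus.algebras["bpmax"].impls,
        choice=lambda l: [max(l)] if l else [],
        properties={UNITARY, SELECTIVE},
        name="maxi",
    )
    prod = interleaved(nus.algebras["pairclass"], maxint)
    pairs = [PairAnswer("x", 1), PairAnswer("x", 3), PairAnswer("y", 2), PairAnswer("y", 5)]
    assert prod.choice(pairs) == [PairAnswer("y", 5)]
    # single class: identical to the lexicographic result
    lex = lexicographic(nus.algebras["pairclass"], maxint)
    single = [PairAnswer("x", 1), PairAnswer("x", 3)]
    assert prod.choice(single) == lex.choice(single)


def test_overlay_forward_returns_first_component_answers(ali):
    prod = overlay(ali.algebras["count"], ali.algebras["enum"])
    assert solve(ali.grammar, prod, ("A", "C")) == [3]


def test_overlay_requires_synoptic_and_enumerative_flags(ali):
    with pytest.raises(AlgebraError):
        overlay(ali.algebras["unit"], ali.algebras["enum"])
    with pytest.raises(AlgebraError):
        overlay(ali.algebras["count"], ali.algebras["score"])


def test_signature_mismatch_is_a_construction_error(ali, nus):
    with pytest.raises(AlgebraError, match="signature"):
        lexicographic(ali.algebras["unit"], nus.algebras["bpmax"])


# -- suchthat ----------------------------------------------------------------

def test_suchthat_keeps_answers_passing_the_predicate(ali):
    st = suchthat(ali.algebras["score"], lambda x: x <= 10)
    assert solve(ali.grammar, st, ("DARLING", "AIRLINE")) == [9]
    st5 = suchthat(ali.algebras["score"], lambda x: x <= 5)
    assert solve(ali.grammar, st5, ("DARLING", "AIRLINE")) == []


def test_suchthat_with_true_predicate_is_a_no_op(nus):
    st = suchthat(nus.instance("cooptnum"), lambda p: True)
    for x in all_strings("GC", 4):
        assert solve(nus.grammar, st, x) == solve(nus.grammar, nus.instance("cooptnum"), x)


# -- classified-count conservation ------------------------------------------

def test_classified_counts_sum_to_total_count(nus):
    census = nus.instance("census")
    for x in all_strings("GCAU", 4):
        per_class = solve(nus.grammar, census, x)
        (total,) = solve(nus.grammar, nus.algebras["count"], x)
        assert sum(p.second for p in per_class) == total


def test_lexicographic_selectivity_on_random_lists(nus):
    import numpy as np

    rng = np.random.default_rng(11)
    prod = lexicographic(nus.algebras["pairclass"], nus.algebras["bpmax"])
    for _ in range(50):
        pairs = [
            PairAnswer(int(rng.integers(0, 4)), int(rng.integers(0, 10)))
            for _ in range(rng.integers(1, 12))
        ]
        out = prod.choice(pairs)
        classes = {p.first for p in pairs}
        for q in out:
            assert q.first in classes
            assert q.second in [p.second for p in pairs if p.first == q.first]


# -- expression parsing ------------------------------------------------------

def test_parse_product_with_parens_and_nesting(flow):
    prod = parse_product("score*(length%mismatch%seqlen)", flow.algebras)
    assert prod.op == "lexicographic"
    assert prod.right.op == "cartesian"
    assert prod.right.left.op == "cartesian"


def test_parse_product_rejects_unknown_names_and_garbage(nus):
    with pytest.raises(AlgebraError, match="unknown algebra"):
        parse_product("bpmax*nothere", nus.algebras)
    with pytest.raises(AlgebraError):
        parse_product("bpmax*(print", nus.algebras)
    with pytest.raises(AlgebraError):
        parse_product("bpmax*", nus.algebras)
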