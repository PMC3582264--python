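"""Generated algebras, property verification, and the algebra contract."""

import pytest

from adpkit import (
    Algebra,
    make_count_algebra,
    solve,
    verify_algebra_properties,
)
from adpkit.algebra import SELECTIVE, UNITARY
from adpkit.errors import AlgebraError


# -- counting ---------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, expected",
    [
        ("A", "C", 3),  # rep; del+ins; ins+del
        ("", "", 1),  # only the empty alignment
        ("AC", "GT", 13),  # Delannoy D(2,2)
    ],
)
def test_alignment_count_matches_enumeration(ali, x, y, expected):
    assert solve(ali.grammar, ali.algebras["count"], (x, y)) == [expected]


def test_count_flags():
    from adpkit import alignment_app

    cnt = alignment_app().algebras["count"]
    assert cnt.has("unitary") and cnt.has("synoptic")


# -- enumeration ------------------------------------------------------------

def test_enum_single_structure_for_unpairable_sequence(nus):
    trees = solve(nus.grammar, nus.algebras["enum"], "AAA")
    assert len(trees) == 1
    t = trees[0]
    assert t.node == "open" and t.children[1].node == "open"


def test_enum_lists_all_seven_structures_of_gcgc(nus):
    # {}, four single pairs (1-2, 1-4, 2-3, 3-4), and the two 2-pair structures
    assert len(solve(nus.grammar, nus.algebras["enum"], "GCGC")) == 7


def test_enum_of_empty_alignment_is_the_nil_candidate(ali):
    trees = solve(ali.grammar, ali.algebras["enum"], ("", ""))
    assert len(trees) == 1 and trees[0].node == "nil"


# -- property verification --------------------------------------------------

def test_min_choice_is_unitary_and_selective(ali):
    report = verify_algebra_properties(ali.algebras["unit"], [[3, 1, 2], [5], [0, 0]])
    assert report.ok


def test_identity_choice_is_selective(nus):
    report = verify_algebra_properties(nus.algebras["enum"], [[1, 2, 2, 3]])
    assert report.ok


def test_sum_choice_is_not_selective(ali):
    cnt = ali.algebras["count"].replace(properties={UNITARY, SELECTIVE})
    report = verify_algebra_properties(cnt, [[1, 1]])
    assert not report.ok
    (fail,) = report.failures()
    assert fail.flag == SELECTIVE
    assert fail.counterexample == ([1, 1], [2])


def test_missing_implementation_is_rejected(ali):
    sig = ali.signature
    with pytest.raises(AlgebraError, match="missing"):
        Algebra(sig, impls={"rep": lambda a, b, m: m}, choice=lambda l: l)


def test_empty_sample_set_is_rejected(ali):
    with pytest.raises(AlgebraError):
        verify_algebra_properties(ali.algebras["unit"], [])
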