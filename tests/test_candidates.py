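"""Candidate-tree construction and evaluation."""

import pytest

from adpkit import CandidateTree, SlotValue, TerminalLeaf, evaluate_candidate
from adpkit.errors import EvaluationError


def char_pair_leaf(i, a, b):
    return TerminalLeaf(
        (SlotValue("CHAR", 0, (i, i + 1), a), SlotValue("CHAR", 1, (i, i + 1), b))
    )


def empty_pair_leaf(i):
    return TerminalLeaf(
        (SlotValue("EMPTY", 0, (i, i), None), SlotValue("EMPTY", 1, (i, i), None))
    )


def columnwise_alignment_tree(x, y):
    """rep columns over two equal-length strings, terminated by nil."""
    assert len(x) == len(y)
    tree = CandidateTree("nil", [empty_pair_leaf(len(x))])
    for i in reversed(range(len(x))):
        tree = CandidateTree("rep", [char_pair_leaf(i, x[i], y[i]), tree])
    return tree


def char_leaf(i, c):
    return TerminalLeaf((SlotValue("CHAR", 0, (i, i + 1), c),))


def rna_two_hairpins():
    """Two pairs over GACGAC: split(pair(G,open(A,nil),C), split(pair..., nil))."""

    def hairpin(i, a, mid, b):
        inner = CandidateTree(
            "open",
            [
                char_leaf(i + 1, mid),
                CandidateTree(
                    "nil", [TerminalLeaf((SlotValue("EMPTY", 0, (i + 2, i + 2)),))]
                ),
            ],
        )
        return CandidateTree("pair", [char_leaf(i, a), inner, char_leaf(i + 2, b)])

    nil6 = CandidateTree("nil", [TerminalLeaf((SlotValue("EMPTY", 0, (6, 6)),))])
    right = CandidateTree("split", [hairpin(3, "G", "A", "C"), nil6])
    return CandidateTree("split", [hairpin(0, "G", "A", "C"), right])


def test_columnwise_edit_candidate_scores_three_mismatches(ali):
    tree = columnwise_alignment_tree("DARLING", "AIRLINE")
    assert evaluate_candidate(tree, ali.algebras["unit"]) == 3
    # the scored variant: 3 mismatches at cost 3 each
    assert evaluate_candidate(tree, ali.algebras["score"]) == 9


def test_rna_candidate_counts_its_base_pairs(nus):
    assert evaluate_candidate(rna_two_hairpins(), nus.algebras["bpmax"]) == 2


def test_any_candidate_counts_once_under_count(ali, nus):
    assert evaluate_candidate(columnwise_alignment_tree("AB", "AB"), ali.algebras["count"]) == 1
    assert evaluate_candidate(rna_two_hairpins(), nus.algebras["count"]) == 1


def test_enum_algebra_round_trips_the_tree(nus):
    tree = rna_two_hairpins()
    assert evaluate_candidate(tree, nus.algebras["enum"]) == tree


def test_unsorted_tree_raises_with_offending_node(ali):
    bad = CandidateTree("rep", [empty_pair_leaf(0)])  # wrong arity
    with pytest.raises(EvaluationError, match="rep"):
        evaluate_candidate(bad, ali.algebras["unit"])
    wrong_kind = CandidateTree(
        "nil", [TerminalLeaf((SlotValue("CHAR", 0, (0, 1), "A"), SlotValue("EMPTY", 1, (0, 0))))]
    )
    with pytest.raises(EvaluationError, match="nil"):
        evaluate_candidate(wrong_kind, ali.algebras["unit"])
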