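"""Brute-force reference semantics and the dynamic Bellman-principle check."""

import pytest

from adpkit import (
    canonical,
    check_bellman,
    enumerate_candidates,
    evaluate_candidate,
    reference_solve,
    solve,
)
from .conftest import all_strings


def test_enumeration_counts(ali, nus):
    assert len(enumerate_candidates(ali.grammar, ("A", "C"))) == 3
    assert len(enumerate_candidates(nus.grammar, "GCGC")) == 7
    # empty input: only the nil candidate
    assert len(enumerate_candidates(ali.grammar, ("", ""))) == 1
    assert len(enumerate_candidates(nus.grammar, "")) == 1


def test_enumeration_cardinality_equals_count_algebra(ali, nus):
    for x in all_strings("GCAU", 4):
        assert len(enumerate_candidates(nus.grammar, x)) == solve(nus.grammar, nus.algebras["count"], x)[0]
    for a in all_strings("AC", 3):
        for b in all_strings("AC", 3):
            assert (
                len(enumerate_candidates(ali.grammar, (a, b)))
                == solve(ali.grammar, ali.algebras["count"], (a, b))[0]
            )


def test_reference_solve_examples(ali, nus):
    assert reference_solve(ali.grammar, ali.algebras["unit"], ("DARLING", "AIRLINE")) == [3]
    assert reference_solve(nus.grammar, nus.algebras["count"], "AAA") == [1]


def test_reference_solve_under_enum_is_the_enumeration(nus):
    for x in all_strings("GC", 3):
        assert reference_solve(nus.grammar, nus.algebras["enum"], x) == enumerate_candidates(
            nus.grammar, x
        )


def test_enumerated_candidates_round_trip_through_evaluation(nus):
    enum = nus.algebras["enum"]
    for t in enumerate_candidates(nus.grammar, "GCAU"):
        assert evaluate_candidate(t, enum) == t


def test_candidate_yields_respect_yield_size_bounds(nus, ali):
    ys = nus.grammar.yields()["N"].per_track[0]
    for x in all_strings("GCA", 4):
        for t in enumerate_candidates(nus.grammar, x):
            (lo, hi) = t.yields(1)[0]
            assert ys[0] <= hi - lo <= ys[1]


def _pair_sampler(rng):
    alpha = list("AC")
    return (
        "".join(rng.choice(alpha, rng.integers(0, 4))),
        "".join(rng.choice(alpha, rng.integers(0, 4))),
    )


def test_bellman_holds_for_additive_minimization(ali):
    report = check_bellman(ali.grammar, ali.algebras["unit"], _pair_sampler, 50, seed=2)
    assert report.ok


def test_bellman_falsifier_catches_second_smallest_choice(ali):
    def second_smallest(l):
        u = sorted(set(l))
        return [u[1]] if len(u) > 1 else list(u[:1])

    broken = ali.algebras["unit"].replace(name="second", choice_fn=second_smallest)
    report = check_bellman(ali.grammar, broken, _pair_sampler, 60, seed=4)
    assert not report.ok
    inputs, got, want = report.counterexample
    assert [canonical(v) for v in got] != [canonical(v) for v in want]


def test_bellman_trivially_holds_for_identity_choice(ali):
    report = check_bellman(ali.grammar, ali.algebras["enum"], _pair_sampler, 15, seed=6)
    assert report.ok
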