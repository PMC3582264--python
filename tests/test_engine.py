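"""Forward evaluation, backtracing schemes, tabulation and sampling."""

from collections import Counter

import pytest

from adpkit import (
    PairAnswer,
    SolveOptions,
    backtrace,
    canonical,
    evaluate_candidate,
    kbest_backtrace,
    lexicographic,
    overlay,
    sample,
    solve,
)
from adpkit.errors import AlgebraError, GrammarError
from .conftest import all_strings


def test_optimal_unit_distance_darling_airline(ali):
    assert solve(ali.grammar, ali.algebras["unit"], ("DARLING", "AIRLINE")) == [3]


def test_bpmax_on_gcagc_and_empty_input(nus):
    assert solve(nus.grammar, nus.algebras["bpmax"], "GCAGC") == [2]
    assert solve(nus.grammar, nus.algebras["bpmax"], "") == [0]


def test_track_count_mismatch_is_an_error(ali):
    with pytest.raises(GrammarError):
        solve(ali.grammar, ali.algebras["unit"], "ABC")


# -- backtracing -------------------------------------------------------------

def test_backtrace_reports_both_gap_placements(ali):
    prod = lexicographic(ali.algebras["score"], ali.algebras["print"])
    got = backtrace(ali.grammar, prod, ("AA", "A"))
    assert set(got) == {
        PairAnswer(4, ("AA", "A-")),
        PairAnswer(4, ("AA", "-A")),
    }


def test_backtrace_without_cooptimal_flag_returns_one(ali):
    prod = lexicographic(ali.algebras["score"], ali.algebras["print"])
    got = backtrace(ali.grammar, prod, ("AA", "A"), SolveOptions(co_optimal=False))
    assert got == [PairAnswer(4, ("AA", "A-"))]


def test_backtrace_on_empty_inputs(ali):
    prod = lexicographic(ali.algebras["score"], ali.algebras["print"])
    assert backtrace(ali.grammar, prod, ("", "")) == [PairAnswer(0, ("", ""))]


def test_backtrace_equals_full_product_solve(nus, ali):
    prod = lexicographic(nus.algebras["bpmax"], nus.algebras["print"])
    for x in all_strings("GCAU", 4):
        assert backtrace(nus.grammar, prod, x) == solve(nus.grammar, prod, x)
    prod2 = lexicographic(ali.algebras["score"], ali.algebras["print"])
    for a in all_strings("AC", 2):
        for b in all_strings("AC", 2):
            assert backtrace(ali.grammar, prod2, (a, b)) == solve(ali.grammar, prod2, (a, b))


def test_backtraced_candidates_rescore_to_the_optimum(nus):
    prod = lexicographic(nus.algebras["bpmax"], nus.algebras["enum"])
    for x in all_strings("GCAU", 4):
        (best,) = solve(nus.grammar, nus.algebras["bpmax"], x)
        for pair in backtrace(nus.grammar, prod, x):
            assert evaluate_candidate(pair.second, nus.algebras["bpmax"]) == best == pair.first


def test_kbest_reports_census_per_score_class(nus):
    prod = lexicographic(nus.algebras["bpmax"], nus.algebras["count"])
    assert kbest_backtrace(nus.grammar, prod, "GCGC", 2) == [
        PairAnswer(2, 2),
        PairAnswer(1, 4),
    ]
    # k=1 reduces to the plain backtrace
    assert kbest_backtrace(nus.grammar, prod, "GCGC", 1) == backtrace(nus.grammar, prod, "GCGC")
    # k beyond the number of distinct scores returns all classes
    assert kbest_backtrace(nus.grammar, prod, "GCGC", 99) == [
        PairAnswer(2, 2),
        PairAnswer(1, 4),
        PairAnswer(0, 1),
    ]
    with pytest.raises(GrammarError):
        kbest_backtrace(nus.grammar, prod, "GCGC", 0)


# -- tabulation --------------------------------------------------------------

def test_results_invariant_under_table_modes(ali, nus):
    for x in all_strings("GCAU", 4):
        want = solve(nus.grammar, nus.algebras["bpmax"], x, SolveOptions(table_mode="all"))
        assert solve(nus.grammar, nus.algebras["bpmax"], x, SolveOptions(table_mode="auto")) == want
        assert solve(nus.grammar, nus.algebras["bpmax"], x, SolveOptions(table_mode=["N"])) == want
    for a in all_strings("AC", 2):
        for b in all_strings("AC", 2):
            want = solve(ali.grammar, ali.algebras["count"], (a, b), SolveOptions(table_mode="all"))
            got = solve(ali.grammar, ali.algebras["count"], (a, b), SolveOptions(table_mode="auto"))
            assert got == want


def test_long_input_does_not_hit_recursion_limits(ali):
    n = 400  # deep enough to exceed the host's default recursion ceiling
    assert solve(ali.grammar, ali.algebras["unit"], ("A" * n, "A" * n)) == [0]


def test_grammars_terminate_on_all_short_inputs(nus):
    for x in all_strings("GC", 8)[-16:]:
        assert solve(nus.grammar, nus.algebras["count"], x)[0] >= 1


# -- sampling ----------------------------------------------------------------

def test_sampling_is_uniform_under_count_weights(ali):
    from scipy import stats

    prod = overlay(ali.algebras["count"], ali.algebras["enum"])
    draws = sample(ali.grammar, prod, ("A", "C"), 3000, seed=42)
    freq = Counter(canonical(t) for t in draws)
    assert len(freq) == 3
    res = stats.chisquare(list(freq.values()))
    assert res.pvalue > 0.01


def test_sampling_edge_cases(ali):
    prod = overlay(ali.algebras["count"], ali.algebras["enum"])
    assert sample(ali.grammar, prod, ("A", "C"), 0, seed=1) == []
    a = sample(ali.grammar, prod, ("AC", "CA"), 25, seed=9)
    b = sample(ali.grammar, prod, ("AC", "CA"), 25, seed=9)
    assert a == b
    with pytest.raises(AlgebraError):
        sample(ali.grammar, lexicographic(ali.algebras["unit"], ali.algebras["enum"]), ("A", "C"), 5)


def test_sampled_candidates_lie_in_the_search_space(nus):
    from adpkit import enumerate_candidates

    prod = overlay(nus.algebras["count"], nus.algebras["enum"])
    space = {canonical(t) for t in enumerate_candidates(nus.grammar, "GCGC")}
    for t in sample(nus.grammar, prod, "GCGC", 40, seed=5):
        assert canonical(t) in space
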