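"""The shipped application bundles: alignment, RNA folding, flowgram alignment."""

import pytest

from adpkit import (
    PairAnswer,
    backtrace,
    enumerate_candidates,
    flowgram_app,
    solve,
)
from adpkit.applications import default_score_table, iround, relative_scores
from adpkit.synth import generate_flowgram_pair, ideal_flowgram
from .conftest import all_strings


def test_alignment_main_instance(ali):
    got = backtrace(ali.grammar, ali.instance("main"), ("DARLING", "AIRLINE"))
    assert got[0].first == 9  # 3 mismatches * 3 beats 1 substitution + 2 gaps = 11
    assert ("DARLING", "AIRLINE") in {p.second for p in got}


def test_single_match_has_unit_distance_zero(ali):
    assert solve(ali.grammar, ali.algebras["unit"], ("X", "X")) == [0]


def test_nussinov_instances(nus):
    assert solve(nus.grammar, nus.instance("cooptnum"), "GCGC") == [PairAnswer(2, 2)]
    assert solve(nus.grammar, nus.instance("cooptimals"), "GCGC") == [
        PairAnswer(2, "()()"),
        PairAnswer(2, "(())"),
    ]
    assert solve(nus.grammar, nus.algebras["bpmax"], "AAAA") == [0]


def test_every_instance_equals_its_oracle_reference(ali, nus):
    from adpkit import reference_solve

    for name in ali.instances:
        inst = ali.instance(name)
        for a in all_strings("AC", 2):
            for b in all_strings("AC", 2):
                assert solve(ali.grammar, inst, (a, b)) == reference_solve(ali.grammar, inst, (a, b))
    for name in nus.instances:
        inst = nus.instance(name)
        for x in all_strings("GCAU", 4):
            assert solve(nus.grammar, inst, x) == reference_solve(nus.grammar, inst, x)


# -- flowgram alignment ------------------------------------------------------

def test_flow_score_algebra_unit_values(flow):
    sc = flow.algebras["score"]
    assert sc.impls["del"]([1.0, 0.0, 0.0, 0.0], 0.0) == 60.0  # 15.0 * 4.0
    mm = flow.algebras["mismatch"]
    assert mm.impls["del"]([1.02, 0.1, 2.9, 0.0], 0) == 4  # 1 + 0 + 3 + 0
    sl = flow.algebras["seqlen"]
    assert sl.impls["rep"](0.98, 2.1, 0) == 2  # max(1, 2)


def test_half_away_from_zero_rounding():
    assert iround(0.5) == 1 and iround(1.5) == 2 and iround(2.49) == 2
    assert iround(-0.5) == -1


def test_identical_flowgram_aligns_to_itself_at_zero(flow):
    f = ideal_flowgram("TTACG")
    x = (list(f.flows), list(f.flows))
    assert solve(flow.grammar, flow.algebras["score"], x) == [0.0]
    got = backtrace(flow.grammar, flow.instance("RKdenoiser"), x)
    assert got[0].first == 0.0
    # an all-replacement alignment spans every column
    assert got[0].second.first.first == len(f.flows)


def test_terminal_indels_only_at_the_outermost_position(flow):
    f1 = ideal_flowgram("TACG")
    f2 = ideal_flowgram("TA")
    trees = enumerate_candidates(flow.grammar, (list(f1.flows), list(f2.flows)))
    assert trees
    for t in trees:
        seen: list = []

        def walk(node, depth):
            if hasattr(node, "node"):
                if node.node in ("ti", "td"):
                    seen.append((node.node, len(node.children)))
                    assert not any(hasattr(c, "node") for c in node.children)
                for c in node.children:
                    walk(c, depth + 1)

        walk(t, 0)
        assert len(seen) <= 1  # at most one terminal indel per candidate


def test_banded_equals_unbanded_with_wide_band(flow):
    clean, noisy = generate_flowgram_pair("TTAACG", 0.2, 0.1, seed=13)
    x = (list(clean.flows), list(noisy.flows))
    wide = flowgram_app(band=max(len(x[0]), len(x[1])))
    want = solve(flow.grammar, flow.algebras["score"], x)
    got = solve(wide.grammar, wide.algebras["score"], x)
    assert got == want


def test_score_table_is_injectable(flow):
    app = flowgram_app(score_table=lambda a, b: 100.0 * abs(iround(a) - iround(b)))
    f = ideal_flowgram("TA")
    g = list(f.flows)
    h = list(f.flows)
    h[0] += 1.0  # one extra count in the T channel
    got = solve(app.grammar, app.algebras["score"], (g, h))
    assert got == [100.0]
    assert default_score_table(0.98, 2.1) == 7.5


def test_relative_scores_postprocessing(flow):
    pair = PairAnswer(30.0, PairAnswer(PairAnswer(10, 3), 6))
    assert relative_scores(pair) == (3.0, 0.5)
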