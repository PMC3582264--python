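"""Grammar validation, yield-size analysis, table design, builtin filters."""

import math

import pytest

from adpkit import (
    ANSWER,
    App,
    CHAR,
    EMPTY,
    FunctionDecl,
    Grammar,
    NT,
    Nonterminal,
    Signature,
    T,
    banded,
    basep,
    check_grammar,
    maxsize,
    minsize,
    table_design,
    yield_size_analysis,
)
from adpkit.errors import GrammarError

INF = math.inf


def tiny_sig():
    return Signature(
        "Tiny",
        tracks=1,
        functions=[
            FunctionDecl("f", (ANSWER,)),
            FunctionDecl("c", (("alphabet",), ANSWER)),
            FunctionDecl("nil", (("void",),)),
        ],
    )


def test_shipped_grammars_are_clean(ali, nus, flow):
    for app in (ali, nus, flow):
        assert check_grammar(app.grammar) == []


def test_epsilon_cycle_is_fatal_and_names_the_nonterminal():
    g = Grammar(
        "loop",
        tiny_sig(),
        axiom="X",
        nonterminals=[Nonterminal("X", [App("f", NT("X"))], choice=True)],
    )
    diags = check_grammar(g)
    assert any(d.fatal and d.code == "epsilon-cycle" and "X" in d.message for d in diags)


def test_arity_mismatch_names_the_function(ali):
    g = Grammar(
        "bad",
        ali.signature,
        axiom="ali",
        nonterminals=[
            Nonterminal("ali", [App("rep", T(CHAR, CHAR))], choice=True),  # missing answer arg
        ],
    )
    diags = check_grammar(g)
    assert any(d.fatal and "rep" in d.message for d in diags)


def test_unreachable_nonterminal_is_warned():
    sig = tiny_sig()
    g = Grammar(
        "unr",
        sig,
        axiom="X",
        nonterminals=[
            Nonterminal("X", [App("nil", T(EMPTY)), App("c", T(CHAR), NT("X"))], choice=True),
            Nonterminal("Y", [App("nil", T(EMPTY))]),
        ],
    )
    diags = check_grammar(g)
    assert any(d.code == "unreachable" and not d.fatal for d in diags)


# -- yield sizes ------------------------------------------------------------

def test_frame_gap_yield_is_exactly_four(flow):
    ys = yield_size_analysis(flow.grammar)
    assert ys["gap"].per_track == ((4, 4),)


def test_rna_axiom_yield_is_unbounded(nus):
    ys = yield_size_analysis(nus.grammar)
    assert ys["N"].per_track == ((0.0, INF),)


def test_nil_only_nonterminal_has_zero_yield(ali):
    g = Grammar(
        "nilonly",
        ali.signature,
        axiom="z",
        nonterminals=[Nonterminal("z", [App("nil", T(EMPTY, EMPTY))], choice=True)],
    )
    ys = yield_size_analysis(g)
    assert ys["z"].per_track == ((0.0, 0.0), (0.0, 0.0))


# -- table design -----------------------------------------------------------

def test_auto_table_design_follows_the_greedy_heuristic(ali, nus):
    # ali: on a cycle and referenced three times; gap referenced twice
    assert table_design(ali.grammar, "auto") == {"ali", "gap"}
    # N: on a cycle
    assert table_design(nus.grammar, "auto") == {"N"}


def test_all_mode_tabulates_everything(flow):
    assert table_design(flow.grammar, "all") == set(flow.grammar.nonterminals)


def test_user_mode_warns_on_omitted_cycle_nonterminal(nus):
    with pytest.warns(UserWarning, match="cycle"):
        table_design(nus.grammar, [])
    with pytest.raises(GrammarError):
        table_design(nus.grammar, ["nope"])


# -- builtin filters --------------------------------------------------------

def test_size_filters():
    x = ("AAAAA",)
    assert not maxsize(4)(x, ((0, 5),), (0,))
    assert maxsize(5)(x, ((0, 5),), (0,))
    assert minsize(4)(x, ((0, 4),), (0,))
    assert not minsize(4)(x, ((0, 3),), (0,))


def test_basep_checks_complementarity_and_short_spans():
    f = basep()
    assert f(("GAAC",), ((0, 4),), (0,))
    assert not f(("AAAA",), ((0, 4),), (0,))
    assert not f(("GC",), ((0, 1),), (0,))  # span shorter than 2


def test_wide_band_accepts_every_subproblem():
    f = banded(10)
    x = ("AAAA", "AAAA")
    for i1 in range(5):
        for i2 in range(5):
            assert f(x, ((i1, 4), (i2, 4)), (0, 1))
    narrow = banded(0, left_pad=0, right_pad=0)
    assert not narrow(x, ((0, 4), (3, 4)), (0, 1))
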