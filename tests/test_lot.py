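"""Expression language: inventory, parsing, printing, typing."""

import numpy as np
import pytest

from lotlearn import (
    AlphabetError,
    ExpressionGrammar,
    Hypothesis,
    LotType,
    LotTypeError,
    ParseError,
    PRIMITIVES,
    parse_expression,
    parse_hypothesis,
    print_expression,
    type_check,
)

S, C, B, SET, P = (
    LotType.STRING,
    LotType.CHAR,
    LotType.BOOL,
    LotType.STRSET,
    LotType.PROB,
)


INVENTORY = [
    # name, arg types, return type, stochastic
    ("pair", (S, C), S, False),
    ("first", (S,), C, False),
    ("rest", (S,), S, False),
    ("insert", (S, S), S, False),
    ("append", (S, S), S, False),
    ("flip", (P,), B, True),
    ("equals", (S, S), B, False),
    ("empty", (S,), B, False),
    ("if", (B, S, S), S, False),
    ("and", (B, B), B, False),
    ("or", (B, B), B, False),
    ("not", (B,), B, False),
    ("singleton", (S,), SET, False),
    ("union", (SET, SET), SET, False),
    ("setminus", (SET, S), SET, False),
    ("sample", (SET,), S, True),
]


@pytest.mark.parametrize("name,args,ret,stochastic", INVENTORY)
def test_primitive_inventory(name, args, ret, stochastic):
    prim = PRIMITIVES[name]
    assert prim.arg_types == args
    assert prim.return_type == ret
    assert prim.stochastic == stochastic


def test_inventory_is_exactly_these():
    assert set(PRIMITIVES) == {name for name, *_ in INVENTORY}


@pytest.mark.parametrize(
    "text",
    [
        "a",
        "ϵ",
        "x",
        "pair(x,a)",
        "append(a,b)",
        "if(flip(1/3),ϵ,F0(x))",
        "sample(union(Σ,{a}))",
        "sample(setminus(Σ,a))",
        "if(equals(x,ϵ),a,first(x))",
        "if(and(empty(x),not(flip(3/4))),Σ,{pair(x,b)})",
    ],
)
def test_parse_print_round_trip(text):
    e = parse_expression(text, "ab")
    # Canonical text reparses to an identical tree.
    assert parse_expression(print_expression(e), "ab") == e


def test_round_trip_on_sampled_expressions():
    g = ExpressionGrammar("ab", n_factors=2)
    rng = np.random.default_rng(7)
    for _ in range(200):
        e = g.sample_expression(rng)
        text = print_expression(e)
        assert parse_expression(text, "ab", n_factors=2) == e


def test_singleton_prints_with_braces():
    e = parse_expression("{a}", "ab")
    assert e.head == "singleton"
    assert print_expression(e) == "{a}"


def test_flip_without_argument_means_one_half():
    e = parse_expression("flip()", "ab")
    assert e == parse_expression("flip(1/2)", "ab")


def test_parse_errors():
    with pytest.raises(ParseError):
        parse_expression("unknownfn(a)", "ab")
    with pytest.raises(ParseError):
        parse_expression("pair(a)", "ab")  # arity
    with pytest.raises(ParseError):
        parse_expression("flip(1/5)", "ab")  # prob constant not allowed
    with pytest.raises(ParseError):
        parse_expression("F1(x)", "ab", n_factors=1)  # index out of range
    with pytest.raises(ParseError):
        parse_expression("F0", "ab")  # factor ref needs an argument
    with pytest.raises(ParseError):
        parse_expression("pair(a,b))", "ab")  # trailing input
    with pytest.raises(AlphabetError):
        parse_expression("pair(x,c)", "ab")  # char outside alphabet


def test_type_errors():
    with pytest.raises(LotTypeError):
        parse_expression("pair(a,rest(x))", "ab")  # second slot wants CHAR
    with pytest.raises(LotTypeError):
        parse_expression("flip(a)", "ab")  # wants PROB
    with pytest.raises(LotTypeError):
        parse_expression("if(x,a,b)", "ab")  # condition must be BOOL
    with pytest.raises(LotTypeError):
        parse_expression("if(flip(1/2),a,Σ)", "ab")  # branches disagree
    with pytest.raises(LotTypeError):
        parse_expression("and(flip(1/2),x)", "ab")


def test_char_promotes_to_string():
    # first() wants STRING; a CHAR argument is accepted.
    e = parse_expression("first(first(x))", "ab")
    assert type_check(e) == C
    # and `if` over CHAR/STRING branches unifies to STRING
    e2 = parse_expression("if(flip(1/2),a,x)", "ab")
    assert type_check(e2) == S


def test_factor_refs_and_reachability():
    h = parse_hypothesis(
        ["pair(if(flip(1/3),ϵ,F0(ϵ)),a)", "append(Fm0(x),F1(x))"], "ab"
    )
    assert h.n_factors == 2
    assert h.entry_index == 1
    assert h.factors[1].children[0].factor_ref() == (0, True)
    assert h.called_factors(1) == {0, 1}
    assert h.all_factors_reachable()
    orphan = parse_hypothesis(["a", "b"], "ab")
    assert not orphan.all_factors_reachable()


def test_size_depth_iter():
    e = parse_expression("pair(append(x,ϵ),a)", "ab")
    assert e.size == 5
    assert e.depth == 3
    assert [n.head for n in e] == ["pair", "append", "x", "ϵ", "a"]


def test_hypothesis_factors_must_be_string_typed():
    with pytest.raises(LotTypeError):
        parse_hypothesis(["empty(x)"], "ab")
    # CHAR-typed factors are fine (promoted).
    parse_hypothesis(["first(x)"], "ab")
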