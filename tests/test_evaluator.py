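"""Evaluator: exact enumeration, mass accounting, memoization, bounds."""

import math

import numpy as np
import pytest

from lotlearn import (
    DEFAULT_BOUNDS,
    EvalBounds,
    ExpressionGrammar,
    apply_primitive,
    monte_carlo_run,
    parse_hypothesis,
    run_factor,
    run_program,
)


def test_geometric_law(an_hypothesis):
    out = run_program(an_hypothesis, "ab")
    for n in range(1, 20):
        assert out.outcomes["a" * n] == pytest.approx((2 / 3) ** (n - 1) / 3, rel=1e-12)
    assert out.outcomes["a"] == pytest.approx(1 / 3, rel=1e-12)
    assert out.total_mass == pytest.approx(1.0, abs=1e-9)


def test_insert_displacement():
    assert apply_primitive("insert", ("abcd", "efg"), "ab") == "abefgcd"
    assert apply_primitive("insert", ("", "xy"), "ab") == "xy"
    assert apply_primitive("insert", ("abc", ""), "ab") == "abc"


def test_apply_primitive_cases():
    assert apply_primitive("pair", ("ab", "c"), "abc") == "abc"
    assert apply_primitive("first", ("abc",), "abc") == "a"
    assert apply_primitive("rest", ("abc",), "abc") == "bc"
    assert apply_primitive("equals", ("a", "a"), "ab") is True
    assert apply_primitive("empty", ("",), "ab") is True
    assert apply_primitive("union", (("a", "b"), ("b", "c")), "abc") == ("a", "b", "c")
    assert apply_primitive("setminus", (("a", "b"), "a"), "ab") == ("b",)
    assert apply_primitive("singleton", ("ab",), "ab") == ("ab",)
    from lotlearn.evaluator import PathError

    with pytest.raises(PathError):
        apply_primitive("first", ("",), "ab")
    with pytest.raises(PathError):
        apply_primitive("rest", ("",), "ab")


def test_three_factor_composition(anbn_hypothesis):
    # F1 appends one b per input character.
    f1 = run_factor(anbn_hypothesis, 1, "ab", input="xyz")
    assert f1.outcomes == {"xyzbbb": pytest.approx(1.0)}
    # The entry factor generates aⁿbⁿ with the geometric law of F0.
    out = run_program(anbn_hypothesis, "ab")
    for s, p in out.outcomes.items():
        n = len(s) // 2
        assert s == "a" * n + "b" * n
        assert p == pytest.approx((2 / 3) ** (n - 1) / 3, rel=1e-9)


def test_memoized_reduplication(abb_hypothesis):
    # F1 = Fm0(sample(Σ)): outer sample picks A, memoized F0 doubles a second
    # sampled B around it -> strings B·A·A with two independent choices.
    out = run_program(abb_hypothesis, "ab")
    assert out.total_mass == pytest.approx(1.0, abs=1e-12)
    assert set(out.outcomes) == {x + y + y for x in "ab" for y in "ab"}
    for p in out.outcomes.values():
        assert p == pytest.approx(0.25)


def test_memoization_replays_choices():
    memo = parse_hypothesis(["append(x,sample(Σ))", "append(Fm0(ϵ),Fm0(ϵ))"], "ab")
    out = run_program(memo, "ab")
    assert set(out.outcomes) == {"aa", "bb"}  # one choice, replayed
    fresh = parse_hypothesis(["append(x,sample(Σ))", "append(F0(ϵ),F0(ϵ))"], "ab")
    out2 = run_program(fresh, "ab")
    assert set(out2.outcomes) == {"aa", "ab", "ba", "bb"}  # two choices


def test_sorted_outcomes_order(an_hypothesis):
    out = run_program(an_hypothesis, "ab")
    ranked = out.sorted_outcomes()
    probs = [p for _, p in ranked]
    assert probs == sorted(probs, reverse=True)
    assert ranked[0][0] == "a"
    assert out.top_k(3) == ranked[:3]


def test_runtime_error_becomes_error_mass():
    h = parse_hypothesis(["first(ϵ)"], "ab")
    out = run_program(h, "ab")
    assert out.outcomes == {}
    assert out.error_mass == pytest.approx(1.0)


def test_unbounded_recursion_becomes_error_mass():
    h = parse_hypothesis(["pair(F0(x),a)"], "ab")
    out = run_program(h, "ab")
    assert out.outcomes == {}
    assert out.error_mass == pytest.approx(1.0)


def test_string_length_cap():
    # append(x,x) under recursion doubles length each level; the length cap
    # must stop it (as error mass) instead of exhausting memory.
    h = parse_hypothesis(["if(flip(1/2),x,F0(append(x,x)))"], "ab")
    out = run_program(h, "ab", input="ab")
    assert out.total_mass == pytest.approx(1.0, abs=1e-6)
    assert out.error_mass > 0
    assert all(len(s) <= DEFAULT_BOUNDS.max_string_length for s in out.outcomes)


def test_probability_floor_sends_mass_to_unexplored(an_hypothesis):
    tight = EvalBounds(min_log_prob=-3.0)
    out = run_program(an_hypothesis, "ab", bounds=tight)
    assert out.unexplored_mass > 0
    assert out.total_mass == pytest.approx(1.0, abs=1e-9)
    # only lengths with log P ≥ −3 appear
    assert set(out.outcomes) <= {"a" * n for n in range(1, 8)}


def test_mass_conservation_on_random_programs(grammar_ab3):
    rng = np.random.default_rng(123)
    for _ in range(60):
        h = grammar_ab3.sample_hypothesis(rng)
        out = run_program(h, "ab")
        assert -1e-9 <= out.total_mass <= 1.0 + 1e-6


def test_monte_carlo_agrees_with_enumeration(an_hypothesis, abb_hypothesis):
    for h in (an_hypothesis, abb_hypothesis):
        out = run_program(h, "ab")
        mc = monte_carlo_run(h, "ab", n_samples=20000, seed=9)
        tv = 0.5 * sum(
            abs(mc.get(s, 0.0) - p) for s, p in out.outcomes.items()
        ) + 0.5 * sum(p for s, p in mc.items() if s not in out.outcomes)
        assert tv < 0.03


def test_entry_index_override(anbn_hypothesis):
    # entry_index=0 runs the aⁿ factor directly.
    out = run_program(anbn_hypothesis, "ab", entry_index=0)
    assert all(set(s) == {"a"} for s in out.outcomes)


def test_deterministic_program_single_path():
    h = parse_hypothesis(["append(pair(x,a),b)"], "ab")
    out = run_program(h, "ab", input="b")
    assert out.outcomes == {"bab": pytest.approx(1.0)}
    assert out.unexplored_mass == 0.0 and out.error_mass == 0.0


def test_bounds_validation():
    with pytest.raises(AssertionError):
        EvalBounds(min_log_prob=1.0)
    with pytest.raises(AssertionError):
        EvalBounds(max_steps=0)
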