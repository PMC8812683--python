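"""MCMC machinery: proposals, scoring, posterior sets, determinism."""

import math

import numpy as np
import pytest

from lotlearn import (
    Dataset,
    ExpressionGrammar,
    InferenceConfig,
    NoiseModel,
    PosteriorSet,
    ScoreContext,
    merge_posteriors,
    mh_step,
    parse_hypothesis,
    propose,
    run_parallel_tempering,
    search_over_factor_counts,
    type_check,
)
from lotlearn.evaluator import DEFAULT_BOUNDS
from lotlearn.inference import ChainState, ConfigError
from lotlearn.lot import LotType


def test_propose_hastings_ratio_on_single_node(grammar_ab):
    # With a single-node factor the proposal must regenerate the root, so
    # the Hastings ratio has a closed form we can recompute.
    h = parse_hypothesis(["a"], "ab")
    rng = np.random.default_rng(3)
    for _ in range(50):
        prop = propose(h, grammar_ab, rng)
        if prop is None:
            continue
        h_new, log_h = prop
        n_new = h_new.factors[0].size
        log_fwd = -math.log(1) + grammar_ab.log_prob_expression(h_new.factors[0])
        log_rev = -math.log(n_new) + grammar_ab.log_prob_expression(h.factors[0])
        assert log_h == pytest.approx(log_rev - log_fwd, rel=1e-12)


def test_propose_yields_well_typed_reachable_hypotheses():
    g = ExpressionGrammar("ab", n_factors=2)
    h = parse_hypothesis(["pair(F1(x),a)", "append(x,F0(ϵ))"], "ab")
    rng = np.random.default_rng(8)
    produced = 0
    for _ in range(200):
        prop = propose(h, g, rng)
        if prop is None:
            continue
        produced += 1
        h_new, _ = prop
        assert h_new.all_factors_reachable()
        for f in h_new.factors:
            assert type_check(f) in (LotType.STRING, LotType.CHAR)
        assert math.isfinite(g.log_prior(h_new))
    assert produced > 100  # most proposals are structurally valid


def test_mh_step_moves_toward_better_hypotheses(grammar_ab):
    data = Dataset(["a"] * 5)
    ctx = ScoreContext(grammar_ab, data, NoiseModel(), DEFAULT_BOUNDS)
    bad = parse_hypothesis(["b"], "ab")
    lp, ll = ctx.score(bad)
    state = ChainState(bad, lp, ll, temperature=1.0)
    rng = np.random.default_rng(0)
    for _ in range(500):
        state = mh_step(state, ctx, rng)
    lp_b, ll_b = ctx.score(bad)
    assert state.log_prior + state.log_lik > lp_b + ll_b


def test_score_context_caches(grammar_ab):
    data = Dataset(["a"])
    ctx = ScoreContext(grammar_ab, data, NoiseModel(), DEFAULT_BOUNDS)
    h = parse_hypothesis(["a"], "ab")
    first = ctx.score(h)
    assert ctx.score(parse_hypothesis(["a"], "ab")) == first
    assert len(ctx._cache) == 1


def test_posterior_set_dedupe_and_weights():
    ps = PosteriorSet(capacity=10)
    a = parse_hypothesis(["a"], "ab")
    b = parse_hypothesis(["b"], "ab")
    ps.add(a, -1.0, -1.0)
    ps.add(parse_hypothesis(["a"], "ab"), -99.0, -99.0)  # duplicate form ignored
    ps.add(b, -1.0, -2.0)
    ps.add(parse_hypothesis(["x"], "ab"), -math.inf, 0.0)  # non-finite skipped
    entries = ps.entries()
    assert len(entries) == 2
    assert entries[0][0] is a  # best first
    assert sum(w for *_, w in entries) == pytest.approx(1.0)
    assert entries[0][3] / entries[1][3] == pytest.approx(math.e)
    assert ps.map_hypothesis() is a


def test_posterior_set_capacity_keeps_best():
    ps = PosteriorSet(capacity=5)
    for i in range(40):
        ps.add(parse_hypothesis(["pair(" * i + "x" + ",a)" * i or "x"], "ab"), -float(i), 0.0)
    entries = ps.entries()
    assert len(entries) == 5
    assert [e[1] for e in entries] == [-0.0, -1.0, -2.0, -3.0, -4.0]


def test_posterior_merge_renormalizes():
    a = PosteriorSet()
    b = PosteriorSet()
    a.add(parse_hypothesis(["a"], "ab"), -1.0, 0.0)
    b.add(parse_hypothesis(["b"], "ab"), -1.0, 0.0)
    merged = merge_posteriors([a, b])
    weights = [w for *_, w in merged.entries()]
    assert weights == pytest.approx([0.5, 0.5])


def test_posterior_jsonl_round_trip():
    ps = PosteriorSet()
    ps.add(parse_hypothesis(["pair(if(flip(1/3),ϵ,F0(ϵ)),a)"], "ab"), -8.0, -3.0)
    ps.add(parse_hypothesis(["a"], "ab"), -2.0, -9.0)
    again = PosteriorSet.from_jsonl(ps.to_jsonl(), "ab")
    assert [(str(h), lp, ll) for h, lp, ll, _ in again.entries()] == [
        (str(h), lp, ll) for h, lp, ll, _ in ps.entries()
    ]


def test_run_is_seed_deterministic(grammar_ab):
    data = Dataset(["a", "aa", "a"])
    cfg = InferenceConfig(steps=150)
    a = run_parallel_tempering(data, grammar_ab, cfg, seed=5).to_jsonl()
    b = run_parallel_tempering(data, grammar_ab, cfg, seed=5).to_jsonl()
    assert a == b


def test_search_over_factor_counts_smoke():
    data = Dataset(["a", "aa"])
    cfg = InferenceConfig(steps=100)
    sets = search_over_factor_counts(data, "ab", cfg, seed=1, factor_counts=(1, 2))
    assert set(sets) == {1, 2}
    merged = merge_posteriors(list(sets.values()))
    assert len(merged) > 0
    assert all(h.n_factors in (1, 2) for h, *_ in merged.entries())


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        InferenceConfig(t_min=0.5)
    with pytest.raises(ConfigError):
        InferenceConfig(t_max=1.0, t_min=1.2)
    with pytest.raises(ConfigError):
        InferenceConfig(n_chains=0)
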