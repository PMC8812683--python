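"""Posterior-weighted scoring, memorization baseline, curves, probes."""

import math

import numpy as np
import pytest

from lotlearn import (
    Dataset,
    EvalConfig,
    ExpressionGrammar,
    InferenceConfig,
    PosteriorSet,
    f_score,
    generalization_matrix,
    get_language,
    language_precision_recall,
    learning_curve,
    memorized_f,
    parse_hypothesis,
    posterior_precision_recall,
    run_program,
    sample_dataset,
)
from lotlearn.evaluation import EvalError, curve_to_tsv


def _single(h, lp=-1.0, ll=-1.0):
    ps = PosteriorSet()
    ps.add(h, lp, ll)
    return ps


def test_f_score():
    assert f_score(0.0, 0.0) == 0.0
    assert f_score(1.0, 1.0) == 1.0
    assert f_score(0.5, 1.0) == pytest.approx(2 / 3)


def test_posterior_precision_recall_single_hypothesis(an_hypothesis):
    ps = _single(an_hypothesis)
    data = Dataset(["a", "a", "aa", "aaa"])
    cfg = EvalConfig(k_top=25)
    precision, recall = posterior_precision_recall(ps, data, cfg, "ab")
    # Hypothesis top-25 are a..a^25; 3 of them observed.
    assert precision == pytest.approx(3 / 25)
    # All 3 observed strings are generable.
    assert recall == pytest.approx(1.0)


def test_language_precision_recall_true_program(an_hypothesis):
    ps = _single(an_hypothesis)
    precision, recall = language_precision_recall(ps, get_language("an"))
    assert precision == pytest.approx(1.0)
    assert recall > 0.95  # the floor truncates the longest of the top 25


def test_weighted_mixture():
    good = parse_hypothesis(["pair(if(flip(1/3),ϵ,F0(ϵ)),a)"], "ab")
    bad = parse_hypothesis(["b"], "ab")
    ps = PosteriorSet()
    w_good = 0.75
    ps.add(good, math.log(w_good), 0.0)
    ps.add(bad, math.log(1 - w_good), 0.0)
    precision, _ = language_precision_recall(ps, get_language("an"))
    # bad's single string is not in aⁿ: precision = w_good·1 + (1−w_good)·0
    assert precision == pytest.approx(w_good)


def test_eq3_matches_brute_force_reimplementation(grammar_ab):
    # Independent, naive recomputation of the weighted scores.
    rng = np.random.default_rng(77)
    cfg = EvalConfig(k_top=10)
    lang = get_language("an")
    for _ in range(10):
        ps = PosteriorSet()
        while len(ps) < 4:
            h = grammar_ab.sample_hypothesis(rng)
            out = run_program(h, "ab")
            if out.outcomes:
                ps.add(h, grammar_ab.log_prior(h), -float(rng.random()))
        data = sample_dataset(lang, 20, seed=int(rng.integers(1 << 30)))
        got_p, got_r = posterior_precision_recall(ps, data, cfg, "ab")
        observed = set(data.counts)
        data_top = data.top_k(cfg.k_top)
        exp_p = exp_r = 0.0
        for h, _, _, w in ps.entries():
            dist = run_program(h, "ab")
            top = [s for s, _ in dist.top_k(cfg.k_top)]
            exp_p += w * len([s for s in top if s in observed]) / len(top)
            exp_r += w * len([s for s in data_top if s in dist.outcomes]) / len(data_top)
        assert got_p == pytest.approx(exp_p, abs=1e-12)
        assert got_r == pytest.approx(exp_r, abs=1e-12)


def test_memorizer_worked_example():
    # D = {ab × 3} against aⁿbⁿ: precision 1, recall 1/25.
    f = memorized_f(Dataset(["ab"] * 3), get_language("anbn"), EvalConfig(k_top=25))
    assert f == pytest.approx(2 * (1 / 25) / (1 + 1 / 25))


def test_memorizer_improves_with_data():
    lang = get_language("an")
    cfg = EvalConfig(k_top=25)
    small = memorized_f(sample_dataset(lang, 10, seed=0), lang, cfg)
    large = memorized_f(sample_dataset(lang, 100000, seed=0), lang, cfg)
    assert small < 0.95 < large


def test_empty_posterior_raises():
    with pytest.raises(EvalError):
        posterior_precision_recall(PosteriorSet(), Dataset(["a"]), EvalConfig(), "ab")


def test_learning_curve_smoke():
    lang = get_language("an")
    cfg = EvalConfig(k_top=10, data_schedule=(1, 3))
    icfg = InferenceConfig(steps=60)
    points = learning_curve(lang, cfg, icfg, factor_counts=(1,), seed=4)
    assert [p.n_tokens for p in points] == [1, 3]
    for p in points:
        assert 0 <= p.f <= 1 and 0 <= p.memorized_f <= 1
    tsv = curve_to_tsv(points)
    assert tsv.splitlines()[0].startswith("n_tokens\t")
    assert len(tsv.splitlines()) == 3


def test_generalization_matrix(an_hypothesis):
    ps = _single(an_hypothesis)
    data = Dataset(["a", "aa"])
    probes, rows, weights = generalization_matrix(
        ps, data, ["aaa", "b", "aa"], "ab"
    )
    assert probes == ["aaa", "b"]  # "aa" occurs in the data → dropped
    assert len(rows) == 1 and weights == [pytest.approx(1.0)]
    assert rows[0][0] == pytest.approx(math.log((2 / 3) ** 2 / 3))
    assert rows[0][1] == -math.inf


def test_generalization_matrix_dedupes_patterns(an_hypothesis):
    ps = PosteriorSet()
    # Two distinct printed forms computing the same distribution.
    ps.add(parse_hypothesis(["pair(if(flip(1/3),ϵ,F0(ϵ)),a)"], "ab"), -1.0, 0.0)
    ps.add(parse_hypothesis(["pair(if(flip(1/3),ϵ,F0(x)),a)"], "ab"), -1.1, 0.0)
    probes, rows, weights = generalization_matrix(ps, Dataset(["a"]), ["aa"], "ab")
    assert len(rows) == 1  # identical generalization rows are merged
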