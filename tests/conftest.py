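"""Shared fixtures: canonical example hypotheses and small grammars."""

import pytest

from lotlearn import ExpressionGrammar, parse_hypothesis

#: Single-factor program generating aⁿ with geometric length, stop prob 1/3.
AN_TEXT = ["pair(if(flip(1/3),ϵ,F0(ϵ)),a)"]

#: Three-factor program generating aⁿbⁿ: F0 builds aⁿ, F1 appends one b per
#: input character (recursing on rest(x)), F2 composes them (entry factor).
ANBN_TEXTS = [
    "pair(if(flip(1/3),ϵ,F0(ϵ)),a)",
    "if(empty(x),ϵ,append(pair(ϵ,first(x)),pair(F1(rest(x)),b)))",
    "F1(F0(ϵ))",
]

#: Two-factor reduplication program (ABB pattern): F0 doubles its argument
#: after a sampled syllable; F1 feeds it a sampled syllable, memoized.
ABB_TEXTS = [
    "append(append(sample(Σ),x),x)",
    "Fm0(sample(Σ))",
]


@pytest.fixture(scope="session")
def an_hypothesis():
    return parse_hypothesis(AN_TEXT, "ab")


@pytest.fixture(scope="session")
def anbn_hypothesis():
    return parse_hypothesis(ANBN_TEXTS, "ab")


@pytest.fixture(scope="session")
def abb_hypothesis():
    return parse_hypothesis(ABB_TEXTS, "ab")


@pytest.fixture(scope="session")
def grammar_ab():
    return ExpressionGrammar("ab", n_factors=1)


@pytest.fixture(scope="session")
def grammar_ab3():
    return ExpressionGrammar("ab", n_factors=3)
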