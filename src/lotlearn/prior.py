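"""PCFG prior over expressions: P(H) and prior sampling.

The prior on hypotheses is a probabilistic context-free grammar whose
nonterminals are the expression types.  For each *requested* type the
productions are the terminals of that type plus every primitive whose
return type is (promotable to) it; a tree's probability is the product of
its production probabilities, so larger programs are automatically less
probable — the simplicity bias.

Production weights are not dictated by the model family, so the default is
the standard one: within each requested type, the terminal productions
share a fixed ``terminal_mass`` uniformly and the operator productions
share the remainder uniformly.  ``terminal_mass`` defaults to 0.7, which
keeps the branching process subcritical (finite expected tree size; checked
at construction via the spectral radius of the mean offspring matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .lot import (
    EPSILON,
    IF_BRANCH_TYPES,
    PRIMITIVES,
    PROB_NAMES,
    SIGMA,
    Expression,
    Hypothesis,
    LotType,
)

__all__ = ["ExpressionGrammar", "DepthError", "GrammarError"]

S, C, B, SET, P = (
    LotType.STRING,
    LotType.CHAR,
    LotType.BOOL,
    LotType.STRSET,
    LotType.PROB,
)


class DepthError(RuntimeError):
    """Prior sampling exceeded the hard depth cap."""


class GrammarError(ValueError):
    """Invalid grammar configuration (e.g. supercritical weights)."""


@dataclass(frozen=True)
class Production:
    head: str
    arg_types: Tuple[LotType, ...]
    logp: float


class ExpressionGrammar:
    """The PCFG defining P(H) for a given alphabet and factor count.

    Parameters
    ----------
    alphabet:
        Ordered single-character symbols Σ of the language.
    n_factors:
        Number of factors F0 … F_{n−1}; each contributes plain and
        memoized call productions (Fi, Fmi) under STRING.
    terminal_mass:
        Total production probability given to terminal symbols within each
        requested type (split uniformly among them); operators share the
        rest uniformly.
    max_depth:
        Hard recursion cap for prior sampling.
    """

    def __init__(
        self,
        alphabet: Sequence[str],
        n_factors: int = 1,
        terminal_mass: float = 0.7,
        max_depth: int = 32,
    ):
        if not 1 <= n_factors <= 4:
            raise GrammarError("n_factors must be in 1..4")
        if not alphabet:
            raise GrammarError("alphabet must be nonempty")
        for ch in alphabet:
            if len(ch) != 1 or ch in ("x", "F", EPSILON, SIGMA):
                raise GrammarError(f"illegal alphabet symbol {ch!r}")
        if len(set(alphabet)) != len(alphabet):
            raise GrammarError("alphabet symbols must be distinct")
        if not 0.0 < terminal_mass < 1.0:
            raise GrammarError("terminal_mass must be in (0,1)")
        self.alphabet = tuple(alphabet)
        self.n_factors = n_factors
        self.terminal_mass = terminal_mass
        self.max_depth = max_depth
        self._productions = {t: self._build(t) for t in LotType}
        self._index = {
            t: {p.head: p for p in prods} for t, prods in self._productions.items()
        }
        self._check_subcritical()

    # -- construction ------------------------------------------------------

    def _build(self, req: LotType) -> Tuple[Production, ...]:
        terminals: list = []
        ops: list = []  # (head, arg_types)
        if req == S:
            terminals = [EPSILON, "x"] + list(self.alphabet)
        elif req == C:
            terminals = list(self.alphabet)
        elif req == SET:
            terminals = [SIGMA]
        elif req == P:
            terminals = list(PROB_NAMES)
        for prim in PRIMITIVES.values():
            if prim.polymorphic:
                continue  # `if` handled per branch type below
            rt = prim.return_type
            if rt == req or (req == S and rt == C):
                ops.append((prim.name, prim.arg_types))
        if req in IF_BRANCH_TYPES and req != C:
            ops.append(("if", (B, req, req)))
        for i in range(self.n_factors):
            if req == S:
                ops.append((f"F{i}", (S,)))
                ops.append((f"Fm{i}", (S,)))
        out = []
        if terminals and ops:
            lt = math.log(self.terminal_mass / len(terminals))
            lo = math.log((1.0 - self.terminal_mass) / len(ops))
        elif terminals:
            lt, lo = math.log(1.0 / len(terminals)), 0.0
        else:
            lt, lo = 0.0, math.log(1.0 / len(ops))
        for head in terminals:
            out.append(Production(head, (), lt))
        for head, args in ops:
            out.append(Production(head, args, lo))
        return tuple(out)

    def _check_subcritical(self) -> None:
        types = list(LotType)
        M = np.zeros((len(types), len(types)))
        for i, t in enumerate(types):
            for prod in self._productions[t]:
                for at in prod.arg_types:
                    M[i, types.index(at)] += math.exp(prod.logp)
        radius = max(abs(np.linalg.eigvals(M)))
        if radius >= 1.0:
            raise GrammarError(
                f"supercritical grammar (mean-offspring spectral radius {radius:.3f}); "
                "increase terminal_mass"
            )
        self.offspring_spectral_radius = float(radius)

    # -- scoring -----------------------------------------------------------

    def productions(self, req: LotType) -> Tuple[Production, ...]:
        return self._productions[req]

    def production_logp(self, req: LotType, head: str) -> float:
        prod = self._index[req].get(head)
        if prod is None:
            raise GrammarError(f"no production {head!r} for requested type {req}")
        return prod.logp

    def log_prob_expression(self, e: Expression, req: LotType = S) -> float:
        """log P of one tree under the PCFG, rooted at requested type ``req``."""
        prod = self._index[req].get(e.head)
        if prod is None:
            raise GrammarError(f"no production {e.head!r} for requested type {req}")
        total = prod.logp
        for child, at in zip(e.children, prod.arg_types):
            total += self.log_prob_expression(child, at)
        return total

    def log_prior(self, h: Hypothesis) -> float:
        """log P(H): factors are independent draws rooted at STRING."""
        if h.n_factors != self.n_factors:
            raise GrammarError(
                f"hypothesis has {h.n_factors} factors, grammar expects {self.n_factors}"
            )
        return sum(self.log_prob_expression(f, S) for f in h.factors)

    # -- sampling ----------------------------------------------------------

    def sample_expression(
        self,
        rng: np.random.Generator,
        req: LotType = S,
        _depth: int = 0,
    ) -> Expression:
        """Draw a well-typed expression from the PCFG at requested type ``req``."""
        if _depth > self.max_depth:
            raise DepthError(f"prior sample exceeded depth {self.max_depth}")
        prods = self._productions[req]
        weights = np.exp([p.logp for p in prods])
        choice = prods[rng.choice(len(prods), p=weights / weights.sum())]
        children = tuple(
            self.sample_expression(rng, at, _depth + 1) for at in choice.arg_types
        )
        return Expression(choice.head, children)

    def sample_hypothesis(self, rng: np.random.Generator) -> Hypothesis:
        while True:
            try:
                factors = tuple(
                    self.sample_expression(rng, S) for _ in range(self.n_factors)
                )
            except DepthError:
                continue
            h = Hypothesis(factors)
            if h.all_factors_reachable():
                return h

    def request_types(self, h: Hypothesis) -> list:
        """Requested type of every node, in the order of ``iter(h)`` per factor.

        Used by subtree-regeneration proposals, which must regenerate at
        the type the PCFG requested at that slot.
        """
        out = []

        def walk(e: Expression, req: LotType) -> None:
            out.append(req)
            prod = self._index[req].get(e.head)
            if prod is None:
                raise GrammarError(f"no production {e.head!r} for requested type {req}")
            for child, at in zip(e.children, prod.arg_types):
                walk(child, at)

        for f in h.factors:
            walk(f, S)
        return out
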