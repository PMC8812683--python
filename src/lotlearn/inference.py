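"""Posterior search: Metropolis–Hastings with subtree-regeneration proposals
inside an adaptive parallel-tempering scheme.

The target density is P(H|D) ∝ P(H)·P(D|H); each chain runs at a
temperature T ≥ 1 which divides the data log likelihood only (the prior is
not tempered).  Proposals pick one node uniformly at random across all
factor trees and regenerate that subtree from the PCFG conditioned on the
type requested at that slot; proposals in which some factor is unreachable
from the entry factor are rejected outright.  Adjacent chains periodically
propose state swaps, and the temperature ladder is adapted by stochastic
approximation toward a uniform adjacent swap-acceptance rate.

Wall-clock swap/adaptation scheduling is replaced by step counts for
reproducibility; every run is fully determined by its seed.

The search output is a :class:`PosteriorSet`: the top-N (default 500)
distinct hypotheses encountered anywhere in the run, scored at T = 1, with
posterior weights renormalized to sum to one over the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .evaluator import DEFAULT_BOUNDS, EvalBounds, run_program
from .likelihood import Dataset, LikelihoodError, NoiseModel, data_log_likelihood
from .lot import Expression, Hypothesis, LotType
from .prior import DepthError, ExpressionGrammar

__all__ = [
    "ConfigError",
    "InferenceConfig",
    "ChainState",
    "PosteriorSet",
    "ScoreContext",
    "propose",
    "mh_step",
    "run_parallel_tempering",
    "search_over_factor_counts",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of one tempering run.

    ``steps`` is the number of MH proposals per chain.  The defaults are
    sized for desk-scale languages; the original wall-clock budgets are
    replaced by these step counts.
    """

    n_chains: int = 5
    t_min: float = 1.0
    t_max: float = 1.2
    steps: int = 2000
    swap_every: int = 100
    adapt_every: int = 2000
    adapt_rate: float = 0.3
    swap_target: float = 0.234
    posterior_capacity: int = 500
    bounds: EvalBounds = DEFAULT_BOUNDS
    noise: NoiseModel = NoiseModel()

    def __post_init__(self):
        if self.n_chains < 1 or self.t_min < 1.0 or self.t_max < self.t_min:
            raise ConfigError("invalid temperature ladder configuration")
        if self.n_chains > 1 and self.t_max == self.t_min == 1.0:
            pass  # degenerate but legal: plain replicated MH


@dataclass
class ChainState:
    hypothesis: Hypothesis
    log_prior: float
    log_lik: float  # untempered, at T = 1
    temperature: float


class PosteriorSet:
    """Top-N hypotheses by unnormalized posterior, deduplicated by their
    canonical printed form, with renormalized weights."""

    def __init__(self, capacity: int = 500):
        self.capacity = capacity
        self._entries: Dict[str, Tuple[Hypothesis, float, float]] = {}

    def add(self, h: Hypothesis, log_prior: float, log_lik: float) -> None:
        key = str(h)
        if key in self._entries or not math.isfinite(log_prior + log_lik):
            return
        self._entries[key] = (h, log_prior, log_lik)
        if len(self._entries) > 2 * self.capacity:
            self._prune()

    def _prune(self) -> None:
        ranked = sorted(
            self._entries.items(), key=lambda kv: -(kv[1][1] + kv[1][2])
        )[: self.capacity]
        self._entries = dict(ranked)

    def entries(self) -> List[Tuple[Hypothesis, float, float, float]]:
        """(hypothesis, log_prior, log_lik, weight), best first, weights
        renormalized over the retained top-N."""
        self._prune()
        ranked = sorted(self._entries.values(), key=lambda e: -(e[1] + e[2]))
        if not ranked:
            return []
        scores = np.array([lp + ll for _, lp, ll in ranked])
        weights = np.exp(scores - logsumexp(scores))
        return [
            (h, lp, ll, float(w)) for (h, lp, ll), w in zip(ranked, weights)
        ]

    def map_hypothesis(self) -> Optional[Hypothesis]:
        entries = self.entries()
        return entries[0][0] if entries else None

    def merge(self, other: "PosteriorSet") -> "PosteriorSet":
        """Union of two sets; relative unnormalized scores are preserved and
        the joint top-N renormalized together."""
        out = PosteriorSet(max(self.capacity, other.capacity))
        for ps in (self, other):
            for h, lp, ll in ps._entries.values():
                out.add(h, lp, ll)
        return out

    def __len__(self) -> int:
        self._prune()
        return len(self._entries)

    def to_jsonl(self) -> str:
        import json

        lines = []
        for rank, (h, lp, ll, w) in enumerate(self.entries()):
            lines.append(
                json.dumps(
                    {
                        "rank": rank,
                        "n_factors": h.n_factors,
                        "factors": [str(f) for f in h.factors],
                        "log_prior": lp,
                        "log_likelihood": ll,
                        "weight": w,
                    }
                )
            )
        return "\n".join(lines)

    @classmethod
    def from_jsonl(cls, text: str, alphabet: Sequence[str]) -> "PosteriorSet":
        import json

        from .lot import parse_hypothesis

        out = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            h = parse_hypothesis(rec["factors"], alphabet)
            out.add(h, rec["log_prior"], rec["log_likelihood"])
        return out


class ScoreContext:
    """Caches (log prior, log likelihood) by canonical printed form.

    MH revisits the same programs constantly; one program's scores are
    independent of chain and temperature, so a run-wide cache is sound.
    """

    def __init__(
        self,
        grammar: ExpressionGrammar,
        data: Dataset,
        noise: NoiseModel,
        bounds: EvalBounds,
        posterior: Optional[PosteriorSet] = None,
    ):
        self.grammar = grammar
        self.data = data
        self.noise = noise
        self.bounds = bounds
        self.posterior = posterior
        self._cache: Dict[str, Tuple[float, float]] = {}

    def score(self, h: Hypothesis) -> Tuple[float, float]:
        key = str(h)
        cached = self._cache.get(key)
        if cached is None:
            lp = self.grammar.log_prior(h)
            out = run_program(h, self.grammar.alphabet, bounds=self.bounds)
            try:
                ll = data_log_likelihood(out, self.data, self.noise)
            except LikelihoodError:
                ll = -math.inf
            cached = (lp, ll)
            if len(self._cache) > 200000:
                self._cache.clear()
            self._cache[key] = cached
        if self.posterior is not None:
            self.posterior.add(h, *cached)
        return cached


# ---------------------------------------------------------------------------
# Proposals
# ---------------------------------------------------------------------------

def _replace_preorder(e: Expression, target: int, new: Expression, counter: list):
    """Replace the node at preorder index ``target`` (counter is a 1-element
    mutable running index)."""
    idx = counter[0]
    counter[0] += 1
    if idx == target:
        return new
    if counter[0] > target and idx != target:
        # target lies outside this subtree only if all children consumed;
        # still need to recurse in order, handled below.
        pass
    children = []
    changed = False
    for c in e.children:
        if counter[0] <= target:
            nc = _replace_preorder(c, target, new, counter)
            changed = changed or (nc is not c)
            children.append(nc)
        else:
            children.append(c)
    if not changed:
        return e
    return Expression(e.head, tuple(children))


def _node_at(e: Expression, target: int) -> Expression:
    for i, node in enumerate(e):
        if i == target:
            return node
    raise IndexError(target)


def propose(
    h: Hypothesis,
    g: ExpressionGrammar,
    rng: np.random.Generator,
) -> Optional[Tuple[Hypothesis, float]]:
    """One subtree-regeneration proposal.

    Returns (proposal, log Hastings ratio log[q(h|h′)/q(h′|h)]), or None if
    the proposal is rejected outright (unreachable factor, or the prior
    sample hit the depth cap).
    """
    req_types = g.request_types(h)  # aligned with per-factor preorder
    sizes = [f.size for f in h.factors]
    total = sum(sizes)
    target = int(rng.integers(total))
    # locate factor and local preorder index
    fi = 0
    while target >= sizes[fi]:
        target -= sizes[fi]
        fi += 1
    offset = sum(sizes[:fi])
    req = req_types[offset + target]
    old_sub = _node_at(h.factors[fi], target)
    try:
        new_sub = g.sample_expression(rng, req)
    except DepthError:
        return None
    new_factor = _replace_preorder(h.factors[fi], target, new_sub, [0])
    factors = list(h.factors)
    factors[fi] = new_factor
    h_new = Hypothesis(tuple(factors))
    if not h_new.all_factors_reachable():
        return None
    n_old = total
    n_new = sum(f.size for f in h_new.factors)
    log_fwd = -math.log(n_old) + g.log_prob_expression(new_sub, req)
    log_rev = -math.log(n_new) + g.log_prob_expression(old_sub, req)
    return h_new, log_rev - log_fwd


def mh_step(
    state: ChainState,
    ctx: ScoreContext,
    rng: np.random.Generator,
) -> ChainState:
    """One Metropolis–Hastings step at the chain's temperature."""
    prop = propose(state.hypothesis, ctx.grammar, rng)
    if prop is None:
        return state
    h_new, log_hastings = prop
    lp_new, ll_new = ctx.score(h_new)
    if not math.isfinite(ll_new):
        return state
    if not math.isfinite(state.log_lik):
        accept = True
    else:
        delta = (
            (lp_new - state.log_prior)
            + (ll_new - state.log_lik) / state.temperature
            + log_hastings
        )
        accept = delta >= 0 or rng.random() < math.exp(delta)
    if accept:
        return ChainState(h_new, lp_new, ll_new, state.temperature)
    return state


# ---------------------------------------------------------------------------
# Parallel tempering
# ---------------------------------------------------------------------------

def _ladder(t_min: float, t_max: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([t_min])
    return np.geomspace(t_min, t_max, n) if t_max > t_min else np.full(n, t_min)


def run_parallel_tempering(
    data: Dataset,
    grammar: ExpressionGrammar,
    cfg: InferenceConfig = InferenceConfig(),
    seed: int = 0,
    initial: Optional[Hypothesis] = None,
) -> PosteriorSet:
    """Run the full tempered search and return the merged posterior set.

    Every evaluated hypothesis (from any chain, at any temperature) enters
    the posterior set with its T = 1 scores.  Fully reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    posterior = PosteriorSet(cfg.posterior_capacity)
    ctx = ScoreContext(grammar, data, cfg.noise, cfg.bounds, posterior)
    temps = _ladder(cfg.t_min, cfg.t_max, cfg.n_chains)
    # log temperature gaps, adapted toward uniform swap acceptance
    log_gaps = (
        np.log(np.diff(np.log(temps))) if cfg.n_chains > 1 and cfg.t_max > cfg.t_min
        else None
    )
    chains: List[ChainState] = []
    for t in temps:
        h = initial if initial is not None else grammar.sample_hypothesis(rng)
        lp, ll = ctx.score(h)
        chains.append(ChainState(h, lp, ll, float(t)))
    swap_attempts = np.zeros(max(cfg.n_chains - 1, 1))
    swap_accepts = np.zeros(max(cfg.n_chains - 1, 1))
    n_adapts = 0
    for step in range(1, cfg.steps + 1):
        for i in range(cfg.n_chains):
            chains[i] = mh_step(chains[i], ctx, rng)
        if cfg.n_chains > 1 and step % cfg.swap_every == 0:
            for i in range(cfg.n_chains - 1):
                a, b = chains[i], chains[i + 1]
                swap_attempts[i] += 1
                if not (math.isfinite(a.log_lik) and math.isfinite(b.log_lik)):
                    continue
                delta = (1.0 / a.temperature - 1.0 / b.temperature) * (
                    b.log_lik - a.log_lik
                )
                if delta >= 0 or rng.random() < math.exp(delta):
                    swap_accepts[i] += 1
                    ha, hb = a.hypothesis, b.hypothesis
                    chains[i] = ChainState(hb, b.log_prior, b.log_lik, a.temperature)
                    chains[i + 1] = ChainState(ha, a.log_prior, a.log_lik, b.temperature)
        if (
            log_gaps is not None
            and step % cfg.adapt_every == 0
            and swap_attempts.min() > 0
        ):
            n_adapts += 1
            rate = swap_accepts / np.maximum(swap_attempts, 1)
            eta = cfg.adapt_rate / math.sqrt(n_adapts)
            log_gaps = log_gaps + eta * (rate - cfg.swap_target)
            log_temps = np.concatenate(
                ([math.log(cfg.t_min)], math.log(cfg.t_min) + np.cumsum(np.exp(log_gaps)))
            )
            new_temps = np.exp(np.clip(log_temps, 0.0, math.log(50.0)))
            for i, t in enumerate(new_temps):
                chains[i] = replace(chains[i], temperature=float(t))
            swap_attempts[:] = 0
            swap_accepts[:] = 0
    return posterior


def search_over_factor_counts(
    data: Dataset,
    alphabet: Sequence[str],
    cfg: InferenceConfig = InferenceConfig(),
    seed: int = 0,
    factor_counts: Sequence[int] = (1, 2, 3, 4),
    terminal_mass: float = 0.7,
) -> Dict[int, PosteriorSet]:
    """Independent tempering runs per factor count.

    Returns one :class:`PosteriorSet` per count; use
    :func:`merge_posteriors` for the jointly renormalized union.
    """
    out: Dict[int, PosteriorSet] = {}
    for i, n in enumerate(factor_counts):
        grammar = ExpressionGrammar(alphabet, n_factors=n, terminal_mass=terminal_mass)
        out[n] = run_parallel_tempering(data, grammar, cfg, seed=seed + 7919 * i)
    return out


def merge_posteriors(sets: Sequence[PosteriorSet]) -> PosteriorSet:
    merged = sets[0]
    for ps in sets[1:]:
        merged = merged.merge(ps)
    return merged
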