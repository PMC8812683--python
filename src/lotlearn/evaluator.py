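"""Program execution by greedy enumeration of stochastic execution paths.

A hypothesis run on an input string defines a distribution over output
strings.  The evaluator explores execution paths best-first in order of
their accumulated probability: each frontier entry is a prefix of choices
made at stochastic sites (``flip`` branches, ``sample`` elements); popping
an entry replays the program deterministically with those choices and
either completes (yielding an output string with the path's probability),
fails (a path-local runtime error or resource-cap violation), or hits a
fresh stochastic site, in which case one child entry per branch is pushed.

Probability accounting is exact and conservative: completed paths land in
``outcomes``; paths abandoned because their log probability fell below the
floor, or never popped before enumeration stopped, are ``unexplored_mass``;
cap violations and runtime errors (``first``/``rest`` of ϵ, ``sample`` of
the empty set) are ``error_mass``.  The three always sum to at most 1 and
to exactly 1 (within float tolerance) when the frontier is exhausted.

Memoized factor calls (``Fmi``) share one memo table per path replay,
keyed by (factor index, argument string): a repeated call within one
execution returns the recorded value instead of making fresh stochastic
choices.

Expressions are compiled once per run into nested Python closures; replays
then avoid per-node dispatch entirely, which matters because best-first
enumeration re-executes the program from scratch at every frontier pop.
"""

from __future__ import annotations

import heapq
import itertools
import math
import sys
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .lot import EPSILON, PROB_NAMES, SIGMA, Expression, Hypothesis

__all__ = [
    "EvalBounds",
    "DEFAULT_BOUNDS",
    "ENGLISH_BOUNDS",
    "OutputDistribution",
    "PathError",
    "run_program",
    "run_factor",
    "monte_carlo_run",
    "apply_primitive",
]


@dataclass(frozen=True)
class EvalBounds:
    """Resource bounds for one top-level evaluation.

    The first four are the standard enumeration bounds (log-probability
    floor, recursion cap, per-path step cap, distinct-output cap);
    ``max_paths`` and ``max_total_steps`` additionally cap, per run, the
    total number of frontier pops and the total steps summed over all path
    replays, so that pathological programs (many output-irrelevant
    stochastic sites, or long paths replayed from scratch at every pop)
    cannot stall the search loop.  ``max_string_length`` bounds intermediate
    strings: concatenation under recursion otherwise doubles length per
    level and exhausts memory long before any step cap fires.
    """

    min_log_prob: float = -15.0
    max_recursion: int = 64
    max_steps: int = 1024
    max_outputs: int = 256
    max_paths: int = 2000
    max_total_steps: int = 200_000
    max_string_length: int = 4096

    def __post_init__(self):
        assert self.min_log_prob < 0
        assert min(self.max_recursion, self.max_steps, self.max_outputs) > 0


DEFAULT_BOUNDS = EvalBounds()
#: Enlarged preset used for the simplified English grammar, which needs a
#: larger enumerated string distribution.
ENGLISH_BOUNDS = EvalBounds(
    min_log_prob=-25.0, max_steps=4096, max_outputs=2048, max_paths=20000,
    max_total_steps=4_000_000,
)


@dataclass
class OutputDistribution:
    """Marginal distribution over generated strings plus unaccounted mass."""

    outcomes: Dict[str, float] = field(default_factory=dict)
    unexplored_mass: float = 0.0
    error_mass: float = 0.0

    @property
    def total_mass(self) -> float:
        return sum(self.outcomes.values()) + self.unexplored_mass + self.error_mass

    def sorted_outcomes(self) -> List[Tuple[str, float]]:
        """Outcomes by descending probability, ties length-then-lexicographic."""
        return sorted(self.outcomes.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))

    def top_k(self, k: int) -> List[Tuple[str, float]]:
        return self.sorted_outcomes()[:k]

    def to_jsonl(self) -> str:
        import json

        return "\n".join(
            json.dumps({"string": s, "probability": p})
            for s, p in self.sorted_outcomes()
        )


class PathError(RuntimeError):
    """A path-local failure: runtime error or resource-cap violation."""


class _NeedChoice(Exception):
    """Raised when execution reaches a stochastic site beyond the given prefix."""

    def __init__(self, options: Sequence[Tuple[object, float]]):
        self.options = list(options)


def apply_primitive(name: str, args: Sequence[object], alphabet: Sequence[str]):
    """Apply a deterministic primitive; stochastic and lazy primitives are
    handled inside the interpreter.  Exposed for direct unit checking of the
    worked string-manipulation semantics (e.g. ``insert``)."""
    if name == "pair":
        return args[0] + args[1]
    if name == "append":
        return args[0] + args[1]
    if name == "first":
        if not args[0]:
            raise PathError("first of empty string")
        return args[0][0]
    if name == "rest":
        if not args[0]:
            raise PathError("rest of empty string")
        return args[0][1:]
    if name == "insert":
        a, b = args
        mid = len(a) // 2
        return a[:mid] + b + a[mid:]
    if name == "equals":
        return args[0] == args[1]
    if name == "empty":
        return args[0] == ""
    if name == "not":
        return not args[0]
    if name == "singleton":
        return (args[0],)
    if name == "union":
        seen = dict.fromkeys(args[0])
        seen.update(dict.fromkeys(args[1]))
        return tuple(seen)
    if name == "setminus":
        return tuple(s for s in args[0] if s != args[1])
    raise ValueError(f"not a deterministic primitive: {name}")


class _Driver:
    """Replays a fixed choice prefix; signals when a fresh site is reached."""

    def __init__(self, choices: Sequence[int]):
        self.choices = choices
        self.pos = 0
        self.logp = 0.0

    def choose(self, options: Sequence[Tuple[object, float]]):
        if self.pos < len(self.choices):
            value, lp = options[self.choices[self.pos]]
            self.pos += 1
            self.logp += lp
            return value
        raise _NeedChoice(options)


class _Sampler:
    """Resolves stochastic sites by forward sampling (Monte-Carlo oracle)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.logp = 0.0

    def choose(self, options: Sequence[Tuple[object, float]]):
        u = self.rng.random()
        acc = 0.0
        for value, lp in options:
            acc += math.exp(lp)
            if u < acc:
                self.logp += lp
                return value
        value, lp = options[-1]  # guard against float round-off
        self.logp += lp
        return value


def _ensure_stack_headroom():
    # Compiled closures use one Python frame per active program node; legal
    # programs stay under max_recursion × expression depth ≈ 2k frames, and
    # anything deeper is converted to path error mass.
    if sys.getrecursionlimit() < 16384:
        sys.setrecursionlimit(16384)


class _Run:
    """Mutable per-replay state: choice driver, step counter, memo table."""

    __slots__ = ("driver", "steps", "memo")

    def __init__(self, driver):
        self.driver = driver
        self.steps = 0
        self.memo: Dict[Tuple[int, str], str] = {}


class _CompiledProgram:
    """A hypothesis compiled to closures ``fn(rt, x, depth) -> value``."""

    def __init__(self, h: Hypothesis, alphabet, bounds: EvalBounds):
        self.alphabet = tuple(alphabet)
        self.bounds = bounds
        self.factors: List[Callable] = [None] * len(h.factors)
        for i, f in enumerate(h.factors):
            self.factors[i] = self._compile(f)

    def run(self, entry: int, x: str, rt: _Run):
        return self.factors[entry](rt, x, 0)

    def _compile(self, e: Expression) -> Callable:
        max_steps = self.bounds.max_steps
        max_rec = self.bounds.max_recursion

        ref = e.factor_ref()
        if ref is not None:
            idx, memoized = ref
            argf = self._compile(e.children[0])
            factors = self.factors  # filled by the time any closure runs
            if memoized:
                def fn(rt, x, depth):
                    rt.steps = s = rt.steps + 1
                    if s > max_steps:
                        raise PathError("step cap exceeded")
                    arg = argf(rt, x, depth)
                    key = (idx, arg)
                    memo = rt.memo
                    if key in memo:
                        return memo[key]
                    if depth >= max_rec:
                        raise PathError("recursion cap exceeded")
                    memo[key] = value = factors[idx](rt, arg, depth + 1)
                    return value
            else:
                def fn(rt, x, depth):
                    rt.steps = s = rt.steps + 1
                    if s > max_steps:
                        raise PathError("step cap exceeded")
                    arg = argf(rt, x, depth)
                    if depth >= max_rec:
                        raise PathError("recursion cap exceeded")
                    return factors[idx](rt, arg, depth + 1)
            return fn

        head = e.head
        if not e.children:
            if head == EPSILON:
                return lambda rt, x, depth: ""
            if head == "x":
                return lambda rt, x, depth: x
            if head == SIGMA:
                sigma = self.alphabet
                return lambda rt, x, depth: sigma
            if head in PROB_NAMES:
                p = PROB_NAMES[head]
                return lambda rt, x, depth: p
            return lambda rt, x, depth: head  # character constant

        subs = [self._compile(c) for c in e.children]

        if head == "flip":
            child = e.children[0]
            if child.head in PROB_NAMES:  # constant-fold the common case
                p = PROB_NAMES[child.head]
                options = [(True, math.log(p)), (False, math.log1p(-p))]

                def fn(rt, x, depth):
                    rt.steps = s = rt.steps + 1
                    if s > max_steps:
                        raise PathError("step cap exceeded")
                    return rt.driver.choose(options)
            else:
                pf = subs[0]

                def fn(rt, x, depth):
                    rt.steps = s = rt.steps + 1
                    if s > max_steps:
                        raise PathError("step cap exceeded")
                    p = pf(rt, x, depth)
                    if not 0.0 < p < 1.0:
                        raise PathError(f"flip probability {p} outside (0,1)")
                    return rt.driver.choose(
                        [(True, math.log(p)), (False, math.log1p(-p))]
                    )
            return fn

        if head == "sample":
            child = e.children[0]
            if child.head == SIGMA and not child.children:
                lp = -math.log(len(self.alphabet))
                options = [(c, lp) for c in self.alphabet]

                def fn(rt, x, depth):
                    rt.steps = s = rt.steps + 1
                    if s > max_steps:
                        raise PathError("step cap exceeded")
                    return rt.driver.choose(options)
            else:
                setf = subs[0]

                def fn(rt, x, depth):
                    rt.steps = s = rt.steps + 1
                    if s > max_steps:
                        raise PathError("step cap exceeded")
                    members = setf(rt, x, depth)
                    if not members:
                        raise PathError("sample from empty set")
                    lp = -math.log(len(members))
                    return rt.driver.choose([(v, lp) for v in members])
            return fn

        if head == "if":
            condf, thenf, elsef = subs

            def fn(rt, x, depth):
                rt.steps = s = rt.steps + 1
                if s > max_steps:
                    raise PathError("step cap exceeded")
                if condf(rt, x, depth):
                    return thenf(rt, x, depth)
                return elsef(rt, x, depth)
            return fn

        if head in ("and", "or"):
            af, bf = subs
            conj = head == "and"

            def fn(rt, x, depth):
                rt.steps = s = rt.steps + 1
                if s > max_steps:
                    raise PathError("step cap exceeded")
                a = bool(af(rt, x, depth))
                if a is conj:  # short-circuit: and needs True, or needs False
                    return bool(bf(rt, x, depth))
                return a
            return fn

        strict = _STRICT_OPS[head]
        if head in ("pair", "append", "insert"):
            af, bf = subs
            max_len = self.bounds.max_string_length

            def fn(rt, x, depth):
                rt.steps = s = rt.steps + 1
                if s > max_steps:
                    raise PathError("step cap exceeded")
                a = af(rt, x, depth)
                b = bf(rt, x, depth)
                if len(a) + len(b) > max_len:
                    raise PathError("string length cap exceeded")
                return strict(a, b)
        elif len(subs) == 1:
            af = subs[0]

            def fn(rt, x, depth):
                rt.steps = s = rt.steps + 1
                if s > max_steps:
                    raise PathError("step cap exceeded")
                return strict(af(rt, x, depth))
        else:
            af, bf = subs

            def fn(rt, x, depth):
                rt.steps = s = rt.steps + 1
                if s > max_steps:
                    raise PathError("step cap exceeded")
                return strict(af(rt, x, depth), bf(rt, x, depth))
        return fn


def _first(s):
    if not s:
        raise PathError("first of empty string")
    return s[0]


def _rest(s):
    if not s:
        raise PathError("rest of empty string")
    return s[1:]


def _insert(a, b):
    mid = len(a) // 2
    return a[:mid] + b + a[mid:]


def _union(a, b):
    seen = dict.fromkeys(a)
    seen.update(dict.fromkeys(b))
    return tuple(seen)


_STRICT_OPS = {
    "pair": lambda a, b: a + b,
    "append": lambda a, b: a + b,
    "first": _first,
    "rest": _rest,
    "insert": _insert,
    "equals": lambda a, b: a == b,
    "empty": lambda s: s == "",
    "not": lambda a: not a,
    "singleton": lambda a: (a,),
    "union": _union,
    "setminus": lambda a, b: tuple(s for s in a if s != b),
}


def run_program(
    h: Hypothesis,
    alphabet: Sequence[str],
    input: str = "",
    bounds: EvalBounds = DEFAULT_BOUNDS,
    entry_index: Optional[int] = None,
) -> OutputDistribution:
    """Enumerate the output distribution of ``h`` on ``input`` (default ϵ).

    ``entry_index`` overrides the entry factor (default: the last one).
    All failures become mass accounting; nothing is raised at top level.
    """
    _ensure_stack_headroom()
    entry = h.entry_index if entry_index is None else entry_index
    prog = _CompiledProgram(h, alphabet, bounds)
    out = OutputDistribution()
    counter = itertools.count()
    frontier: List[Tuple[float, int, Tuple[int, ...]]] = [(0.0, next(counter), ())]
    pops = 0
    total_steps = 0
    while frontier:
        if (
            len(out.outcomes) >= bounds.max_outputs
            or pops >= bounds.max_paths
            or total_steps >= bounds.max_total_steps
        ):
            break
        neg_lp, _, choices = heapq.heappop(frontier)
        pops += 1
        driver = _Driver(choices)
        rt = _Run(driver)
        try:
            value = prog.run(entry, input, rt)
        except _NeedChoice as site:
            total_steps += rt.steps
            base = driver.logp
            for i, (_, lp) in enumerate(site.options):
                child_lp = base + lp
                if child_lp < bounds.min_log_prob:
                    out.unexplored_mass += math.exp(child_lp)
                else:
                    heapq.heappush(
                        frontier, (-child_lp, next(counter), choices + (i,))
                    )
            continue
        except (PathError, RecursionError):
            total_steps += rt.steps
            out.error_mass += math.exp(-neg_lp)
            continue
        total_steps += rt.steps
        prob = math.exp(-neg_lp)
        out.outcomes[value] = out.outcomes.get(value, 0.0) + prob
    for neg_lp, _, _ in frontier:  # mass never popped
        out.unexplored_mass += math.exp(-neg_lp)
    return out


def run_factor(
    h: Hypothesis,
    index: int,
    alphabet: Sequence[str],
    input: str = "",
    bounds: EvalBounds = DEFAULT_BOUNDS,
) -> OutputDistribution:
    """Run one specific factor of ``h`` on ``input``."""
    return run_program(h, alphabet, input=input, bounds=bounds, entry_index=index)


def monte_carlo_run(
    h: Hypothesis,
    alphabet: Sequence[str],
    input: str = "",
    n_samples: int = 10000,
    seed: int = 0,
    bounds: EvalBounds = DEFAULT_BOUNDS,
    entry_index: Optional[int] = None,
) -> Dict[str, float]:
    """Forward-sampling oracle: empirical output string frequencies.

    Runs the program ``n_samples`` times, resolving each stochastic site by
    its stated probability and honoring memoization, truncating runaway
    paths at the same caps (truncated runs are dropped from the counts but
    still consume a sample, so frequencies estimate the same subnormalized
    outcome measure that :func:`run_program` enumerates).
    """
    _ensure_stack_headroom()
    entry = h.entry_index if entry_index is None else entry_index
    prog = _CompiledProgram(h, alphabet, bounds)
    rng = np.random.default_rng(seed)
    counts: Dict[str, int] = {}
    for _ in range(n_samples):
        try:
            value = prog.run(entry, input, _Run(_Sampler(rng)))
        except (PathError, RecursionError):
            continue
        counts[value] = counts.get(value, 0) + 1
    return {s: c / n_samples for s, c in counts.items()}
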