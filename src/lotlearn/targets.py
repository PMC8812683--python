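"""Target formal languages: samplers, top-k enumerators, membership.

Each target is a probability distribution over strings (the ground truth
the learner sees data from), exposing three views:

* ``sample(rng)`` — one string token;
* ``top_k(k)``    — the k highest-probability strings with probabilities
  (exact for parametric families; best-first derivation/path enumeration
  for grammars and machines);
* ``membership(s)`` — whether s is in the language at all.

String lengths (or repetition indices) are geometrically distributed with
stop probability 1/3 by default, matching the flip(1/3) generators used as
worked examples; finite languages are given either uniform weights or a
geometric skew over a fixed enumeration order (configurable per entry).

The registry covers the classic formal-language suite (aⁿ, aⁿbⁿ, aⁿbⁿcⁿ,
Dyck, mirror, copy, crossed dependencies, …), single-character recodings
of artificial-language-learning stimuli (Saffran segmentation stream,
Marcus ABA/ABB, Gómez aXb, Newport–Aslin nonadjacent dependencies, Reber
and Berwick–Pilato machines, Morgan–Newport grammar, Reeder QAXB with
held-out strings), and a simplified English phrase-structure grammar.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .likelihood import Dataset

__all__ = [
    "TargetLanguage",
    "sample_dataset",
    "language_registry",
    "get_language",
    "DEFAULT_STOP_PROB",
]

DEFAULT_STOP_PROB = 1.0 / 3.0

TopK = List[Tuple[str, float]]


class ConfigError(ValueError):
    pass


def _rank_key(item: Tuple[str, float]):
    s, p = item
    return (-p, len(s), s)


class TargetLanguage:
    """Base interface; subclasses implement sample/top_k/membership."""

    name: str
    alphabet: Tuple[str, ...]

    def sample(self, rng: np.random.Generator) -> str:
        raise NotImplementedError

    def top_k(self, k: int) -> TopK:
        raise NotImplementedError

    def membership(self, s: str) -> bool:
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"<TargetLanguage {self.name} Σ={''.join(self.alphabet)}>"


def sample_dataset(t: TargetLanguage, n_tokens: int, seed: int) -> Dataset:
    """n_tokens i.i.d. strings from the target distribution."""
    if n_tokens < 1:
        raise ConfigError("n_tokens must be >= 1")
    rng = np.random.default_rng(seed)
    return Dataset((t.sample(rng) for _ in range(n_tokens)), source_language=t.name)


def _geom_logp(n: int, p: float) -> float:
    return (n - 1) * math.log1p(-p) + math.log(p)


# ---------------------------------------------------------------------------
# Parametric (indexed) families: string = form(indices), indices i.i.d.
# geometric with stop probability p.
# ---------------------------------------------------------------------------

class IndexedLanguage(TargetLanguage):
    def __init__(
        self,
        name: str,
        alphabet: Sequence[str],
        form: Callable[[Tuple[int, ...]], str],
        n_indices: int,
        member: Callable[[str], bool],
        stop_prob: float = DEFAULT_STOP_PROB,
    ):
        self.name = name
        self.alphabet = tuple(alphabet)
        self.form = form
        self.n_indices = n_indices
        self._member = member
        self.stop_prob = stop_prob

    def sample(self, rng: np.random.Generator) -> str:
        idx = tuple(int(rng.geometric(self.stop_prob)) for _ in range(self.n_indices))
        return self.form(idx)

    def index_log_prob(self, idx: Tuple[int, ...]) -> float:
        return sum(_geom_logp(i, self.stop_prob) for i in idx)

    def top_k(self, k: int) -> TopK:
        # best-first over index tuples; distinct tuples give distinct strings
        # for every family registered here.
        start = (1,) * self.n_indices
        seen = {start}
        heap = [(-self.index_log_prob(start), start)]
        out: Dict[str, float] = {}
        while heap and len(out) < k:
            neg_lp, idx = heapq.heappop(heap)
            s = self.form(idx)
            out[s] = out.get(s, 0.0) + math.exp(-neg_lp)
            for j in range(self.n_indices):
                nxt = idx[:j] + (idx[j] + 1,) + idx[j + 1 :]
                if nxt not in seen:
                    seen.add(nxt)
                    heapq.heappush(heap, (-self.index_log_prob(nxt), nxt))
        return sorted(out.items(), key=_rank_key)[:k]

    def membership(self, s: str) -> bool:
        return self._member(s)


class UniformStringsLanguage(TargetLanguage):
    """All nonempty strings over Σ: geometric length, uniform characters."""

    def __init__(self, name: str, alphabet: Sequence[str], stop_prob=DEFAULT_STOP_PROB):
        self.name = name
        self.alphabet = tuple(alphabet)
        self.stop_prob = stop_prob

    def sample(self, rng: np.random.Generator) -> str:
        n = int(rng.geometric(self.stop_prob))
        return "".join(rng.choice(self.alphabet) for _ in range(n))

    def top_k(self, k: int) -> TopK:
        out = []
        length = 1
        while len(out) < k:
            p = math.exp(_geom_logp(length, self.stop_prob)) / len(self.alphabet) ** length
            for chars in itertools.product(self.alphabet, repeat=length):
                out.append(("".join(chars), p))
                if len(out) == k:
                    break
            length += 1
        return out

    def membership(self, s: str) -> bool:
        return len(s) > 0 and all(c in self.alphabet for c in s)


class HalfStringLanguage(TargetLanguage):
    """Languages of the form f(x) for a uniformly random nonempty x over Σ
    (mirror x·xᴿ, copy x·x, square x^|x|): P(s) is the probability of its
    unique witness x."""

    def __init__(self, name, alphabet, combine, member, stop_prob=DEFAULT_STOP_PROB):
        self.name = name
        self.alphabet = tuple(alphabet)
        self.combine = combine
        self._member = member
        self.stop_prob = stop_prob

    def sample(self, rng: np.random.Generator) -> str:
        n = int(rng.geometric(self.stop_prob))
        x = "".join(rng.choice(self.alphabet) for _ in range(n))
        return self.combine(x)

    def top_k(self, k: int) -> TopK:
        out = []
        length = 1
        while len(out) < k:
            p = math.exp(_geom_logp(length, self.stop_prob)) / len(self.alphabet) ** length
            for chars in itertools.product(self.alphabet, repeat=length):
                out.append((self.combine("".join(chars)), p))
                if len(out) == k:
                    break
            length += 1
        return out

    def membership(self, s: str) -> bool:
        return self._member(s)


class FiniteLanguage(TargetLanguage):
    """A finite list of strings with uniform or geometric weights.

    ``extra_members`` lists strings accepted by membership but never
    sampled (held-out strings, as in the Reeder QAXB design).
    """

    def __init__(
        self,
        name: str,
        alphabet: Sequence[str],
        strings: Sequence[str],
        weights: str = "uniform",
        skew: float = DEFAULT_STOP_PROB,
        extra_members: Sequence[str] = (),
    ):
        self.name = name
        self.alphabet = tuple(alphabet)
        self.strings = list(strings)
        self.extra_members = list(extra_members)
        if weights == "uniform":
            self.probs = [1.0 / len(self.strings)] * len(self.strings)
        elif weights == "geometric":
            raw = [(1 - skew) ** i * skew for i in range(len(self.strings))]
            z = sum(raw)
            self.probs = [w / z for w in raw]
        else:
            raise ConfigError(f"unknown weights {weights!r}")
        self._members = set(self.strings) | set(self.extra_members)

    def sample(self, rng: np.random.Generator) -> str:
        return self.strings[int(rng.choice(len(self.strings), p=self.probs))]

    def top_k(self, k: int) -> TopK:
        # membership-bearing held-out strings are part of the language; they
        # carry zero sampling mass and rank after all sampled strings.
        ranked = sorted(zip(self.strings, self.probs), key=_rank_key)
        held = sorted(((s, 0.0) for s in self.extra_members), key=_rank_key)
        return (ranked + held)[:k]

    def membership(self, s: str) -> bool:
        return s in self._members


# ---------------------------------------------------------------------------
# Probabilistic finite-state machines
# ---------------------------------------------------------------------------

class PFSMLanguage(TargetLanguage):
    """States with (symbol, next-state) out-edges; per-state probabilities
    uniform over out-edges plus an optional stop action."""

    def __init__(
        self,
        name: str,
        alphabet: Sequence[str],
        edges: Dict[int, List[Tuple[str, int]]],
        stop_states: Sequence[int],
        start: int = 0,
    ):
        self.name = name
        self.alphabet = tuple(alphabet)
        self.edges = edges
        self.stop_states = set(stop_states)
        self.start = start

    def _options(self, state: int) -> List[Tuple[Optional[str], Optional[int], float]]:
        outs: List[Tuple[Optional[str], Optional[int]]] = list(
            self.edges.get(state, [])
        )
        if state in self.stop_states:
            outs = outs + [(None, None)]
        p = 1.0 / len(outs)
        return [(sym, nxt, p) for sym, nxt in outs]

    def sample(self, rng: np.random.Generator) -> str:
        state, out = self.start, []
        while True:
            options = self._options(state)
            sym, nxt, _ = options[int(rng.integers(len(options)))]
            if sym is None:
                return "".join(out)
            out.append(sym)
            state = nxt

    def top_k(self, k: int, max_pops: int = 100000) -> TopK:
        heap = [(0.0, 0, "", self.start)]
        counter = itertools.count(1)
        found: Dict[str, float] = {}
        pops = 0
        while heap and pops < max_pops:
            neg_lp, _, s, state = heapq.heappop(heap)
            pops += 1
            if state is None:
                found[s] = found.get(s, 0.0) + math.exp(-neg_lp)
                if len(found) >= k and (not heap or -heap[0][0] < math.log(1e-4)):
                    break
                continue
            for sym, nxt, p in self._options(state):
                child = neg_lp - math.log(p)
                if child > 40:  # negligible paths
                    continue
                heapq.heappush(
                    heap,
                    (child, next(counter), s + sym if sym else s, nxt),
                )
        return sorted(found.items(), key=_rank_key)[:k]

    def membership(self, s: str) -> bool:
        states = {self.start}
        for ch in s:
            nxt = set()
            for st in states:
                for sym, to in self.edges.get(st, []):
                    if sym == ch:
                        nxt.add(to)
            if not nxt:
                return False
            states = nxt
        return bool(states & self.stop_states)


# ---------------------------------------------------------------------------
# Weighted context-free grammars
# ---------------------------------------------------------------------------

class WCFGLanguage(TargetLanguage):
    """Weighted CFG: rules[NT] = [(rhs symbols, probability)]."""

    def __init__(
        self,
        name: str,
        alphabet: Sequence[str],
        rules: Dict[str, List[Tuple[Tuple[str, ...], float]]],
        start: str = "S",
        max_expansions: int = 500,
    ):
        self.name = name
        self.alphabet = tuple(alphabet)
        self.rules = rules
        self.start = start
        self.max_expansions = max_expansions
        for nt, prods in rules.items():
            total = sum(p for _, p in prods)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name}: probabilities for {nt} sum to {total}")

    def sample(self, rng: np.random.Generator) -> str:
        while True:  # resample on (rare) expansion-budget overflow
            out: List[str] = []
            stack = [self.start]
            budget = self.max_expansions
            ok = True
            while stack:
                sym = stack.pop()
                if sym not in self.rules:
                    out.append(sym)
                    continue
                budget -= 1
                if budget < 0:
                    ok = False
                    break
                prods = self.rules[sym]
                probs = [p for _, p in prods]
                rhs = prods[int(rng.choice(len(prods), p=probs))][0]
                stack.extend(reversed(rhs))
            if ok:
                return "".join(out)

    def top_k(self, k: int, max_pops: int = 200000) -> TopK:
        """Best-first enumeration of leftmost derivations, aggregating
        duplicate yields (approximate for highly ambiguous grammars)."""
        heap = [(0.0, 0, (self.start,))]
        counter = itertools.count(1)
        found: Dict[str, float] = {}
        pops = 0
        while heap and pops < max_pops:
            neg_lp, _, form = heapq.heappop(heap)
            pops += 1
            i = next((j for j, sym in enumerate(form) if sym in self.rules), None)
            if i is None:
                s = "".join(form)
                found[s] = found.get(s, 0.0) + math.exp(-neg_lp)
                if len(found) >= k + 5 and (not heap or -heap[0][0] < math.log(1e-6)):
                    break
                continue
            if len(form) > 80:
                continue
            for rhs, p in self.rules[form[i]]:
                heapq.heappush(
                    heap,
                    (
                        neg_lp - math.log(p),
                        next(counter),
                        form[:i] + rhs + form[i + 1 :],
                    ),
                )
        return sorted(found.items(), key=_rank_key)[:k]

    def membership(self, s: str) -> bool:
        return _earley_accepts(self.rules, self.start, tuple(s))


def _earley_accepts(rules, start, tokens) -> bool:
    """Earley recognizer over character terminals."""
    GAMMA = "\x00"
    grammar = dict(rules)
    grammar[GAMMA] = [((start,), 1.0)]
    n = len(tokens)
    # chart[i]: set of items (lhs, rhs, dot, origin)
    chart: List[set] = [set() for _ in range(n + 1)]
    chart[0].add((GAMMA, (start,), 0, 0))
    for i in range(n + 1):
        agenda = list(chart[i])
        while agenda:
            item = agenda.pop()
            lhs, rhs, dot, origin = item
            if dot < len(rhs):
                nxt = rhs[dot]
                if nxt in grammar:  # predict
                    for prod, _ in grammar[nxt]:
                        new = (nxt, prod, 0, i)
                        if new not in chart[i]:
                            chart[i].add(new)
                            agenda.append(new)
                elif i < n and tokens[i] == nxt:  # scan
                    new = (lhs, rhs, dot + 1, origin)
                    if new not in chart[i + 1]:
                        chart[i + 1].add(new)
            else:  # complete
                for other in list(chart[origin]):
                    olhs, orhs, odot, oorigin = other
                    if odot < len(orhs) and orhs[odot] == lhs:
                        new = (olhs, orhs, odot + 1, oorigin)
                        if new not in chart[i]:
                            chart[i].add(new)
                            agenda.append(new)
    return (GAMMA, (start,), 1, 0) in chart[n]


# ---------------------------------------------------------------------------
# Special-cased languages
# ---------------------------------------------------------------------------

class ChineseNumeralLanguage(TargetLanguage):
    """{a b^{n1} a b^{n2} … a b^{nk} : n1 > n2 > … > nk ≥ 1}.

    Generative process: n1 ~ geometric(1/3); after emitting a block of
    n_i ≥ 2 b's, continue with probability 1/2 to a block of uniform
    length in 1..n_i−1; a block of one b always ends the string.
    """

    name = "chinese-numeral"
    alphabet = ("a", "b")
    stop_prob = DEFAULT_STOP_PROB

    def sample(self, rng: np.random.Generator) -> str:
        blocks = [int(rng.geometric(self.stop_prob))]
        while blocks[-1] > 1 and rng.random() < 0.5:
            blocks.append(int(rng.integers(1, blocks[-1])))
        return "".join("a" + "b" * n for n in blocks)

    def _log_prob(self, blocks: Sequence[int]) -> float:
        lp = _geom_logp(blocks[0], self.stop_prob)
        for prev, cur in zip(blocks, blocks[1:]):
            lp += math.log(0.5) - math.log(prev - 1)  # continue, choose cur
        if blocks[-1] > 1:
            lp += math.log(0.5)  # chose to stop
        return lp

    def top_k(self, k: int, max_first: int = 14) -> TopK:
        found = []
        for r in range(1, max_first + 1):
            for blocks in itertools.combinations(range(max_first, 0, -1), r):
                if blocks[0] > max_first:
                    continue
                s = "".join("a" + "b" * n for n in blocks)
                found.append((s, math.exp(self._log_prob(blocks))))
        return sorted(found, key=_rank_key)[:k]

    def membership(self, s: str) -> bool:
        if not s.startswith("a"):
            return False
        blocks = [len(part) for part in s[1:].split("a")]
        return all(n >= 1 for n in blocks) and all(
            a > b for a, b in zip(blocks, blocks[1:])
        )


class SaffranLanguage(TargetLanguage):
    """Word-segmentation stream: utterances are concatenations of lexicon
    words (uniform word choice, geometric utterance length), with no
    between-word delimiters.  Default lexicon is four trisyllabic words
    with syllables written as letter pairs/singles, including 'tapiro'."""

    def __init__(
        self,
        lexicon: Sequence[str] = ("tapiro", "golabu", "bidaku", "padoti"),
        stop_prob: float = DEFAULT_STOP_PROB,
    ):
        self.name = "saffran"
        self.lexicon = tuple(lexicon)
        self.alphabet = tuple(sorted(set("".join(lexicon))))
        self.stop_prob = stop_prob

    def sample(self, rng: np.random.Generator) -> str:
        m = int(rng.geometric(self.stop_prob))
        return "".join(
            self.lexicon[int(rng.integers(len(self.lexicon)))] for _ in range(m)
        )

    def top_k(self, k: int) -> TopK:
        found: Dict[str, float] = {}
        m = 1
        while len(found) < k:
            p = math.exp(_geom_logp(m, self.stop_prob)) / len(self.lexicon) ** m
            for words in itertools.product(self.lexicon, repeat=m):
                s = "".join(words)
                found[s] = found.get(s, 0.0) + p
            m += 1
        return sorted(found.items(), key=_rank_key)[:k]

    def membership(self, s: str) -> bool:
        @lru_cache(maxsize=None)
        def seg(t: str) -> bool:
            if not t:
                return True
            return any(t.startswith(w) and seg(t[len(w) :]) for w in self.lexicon)

        return len(s) > 0 and seg(s)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _blocks_member(s: str, pattern: Callable[[Tuple[int, ...]], str], max_n=200):
    """Generic membership for single-index block families by inversion."""
    for n in range(1, max_n):
        t = pattern((n,))
        if t == s:
            return True
        if len(t) > len(s):
            return False
    return False


def _an(idx):
    return "a" * idx[0]


def _make_registry() -> Dict[str, Callable[[], TargetLanguage]]:
    reg: Dict[str, Callable[[], TargetLanguage]] = {}

    def add(name, fn):
        reg[name] = fn

    add("an", lambda: IndexedLanguage(
        "an", "ab", _an, 1,
        lambda s: len(s) > 0 and set(s) == {"a"}))
    add("a123", lambda: FiniteLanguage(
        "a123", "ab", ["a", "aa", "aaa"], weights="geometric"))
    add("abn", lambda: IndexedLanguage(
        "abn", "ab", lambda i: "ab" * i[0], 1,
        lambda s: len(s) > 0 and len(s) % 2 == 0 and s == "ab" * (len(s) // 2)))
    add("sigma-plus", lambda: UniformStringsLanguage("sigma-plus", "ab"))
    add("anbn", lambda: IndexedLanguage(
        "anbn", "ab", lambda i: "a" * i[0] + "b" * i[0], 1,
        lambda s: len(s) > 0 and len(s) % 2 == 0
        and s == "a" * (len(s) // 2) + "b" * (len(s) // 2)))
    add("anbncn", lambda: IndexedLanguage(
        "anbncn", "abc", lambda i: ("a" * i[0]) + ("b" * i[0]) + ("c" * i[0]), 1,
        lambda s: len(s) > 0 and len(s) % 3 == 0
        and s == "a" * (len(s) // 3) + "b" * (len(s) // 3) + "c" * (len(s) // 3)))
    add("anbncndn", lambda: IndexedLanguage(
        "anbncndn", "abcd",
        lambda i: "a" * i[0] + "b" * i[0] + "c" * i[0] + "d" * i[0], 1,
        lambda s: len(s) > 0 and len(s) % 4 == 0
        and s == "".join(c * (len(s) // 4) for c in "abcd")))
    add("anbm", lambda: IndexedLanguage(
        "anbm", "ab", lambda i: "a" * i[0] + "b" * i[1], 2,
        lambda s: len(s) >= 2 and _is_block_pair(s)))
    add("anb2n", lambda: IndexedLanguage(
        "anb2n", "ab", lambda i: "a" * i[0] + "b" * (2 * i[0]), 1,
        lambda s: len(s) > 0 and len(s) % 3 == 0
        and s == "a" * (len(s) // 3) + "b" * (2 * len(s) // 3)))
    add("dyck", _dyck)
    add("xxr", lambda: HalfStringLanguage(
        "xxr", "ab", lambda x: x + x[::-1],
        lambda s: len(s) > 0 and len(s) % 2 == 0 and s == s[::-1]))
    add("xx", lambda: HalfStringLanguage(
        "xx", "ab", lambda x: x + x,
        lambda s: len(s) > 0 and len(s) % 2 == 0
        and s[: len(s) // 2] == s[len(s) // 2 :]))
    add("xlenx", lambda: HalfStringLanguage(
        "xlenx", "ab", lambda x: x * len(x),
        _xlenx_member))
    add("anbmcndm", lambda: IndexedLanguage(
        "anbmcndm", "abcd",
        lambda i: "a" * i[0] + "b" * i[1] + "c" * i[0] + "d" * i[1], 2,
        _anbmcndm_member))
    add("anbmanbmccc", lambda: IndexedLanguage(
        "anbmanbmccc", "abc",
        lambda i: ("a" * i[0] + "b" * i[1]) * 2 + "ccc", 2,
        _anbmanbmccc_member))
    add("chinese-numeral", lambda: ChineseNumeralLanguage())
    add("count", lambda: IndexedLanguage(
        "count", "ab",
        lambda i: "".join("a" + "b" * j for j in range(1, i[0] + 1)), 1,
        lambda s: _blocks_member(
            s, lambda i: "".join("a" + "b" * j for j in range(1, i[0] + 1)))))
    add("golden-mean", lambda: PFSMLanguage(
        "golden-mean", "ab",
        edges={0: [("a", 1), ("b", 2)], 1: [("a", 1), ("b", 2)], 2: [("a", 1)]},
        stop_states=[1, 2]))
    add("a2n", lambda: IndexedLanguage(
        "a2n", "ab", lambda i: "a" * (2 ** i[0]), 1,
        lambda s: len(s) >= 2 and set(s) == {"a"} and (len(s) & (len(s) - 1)) == 0))
    add("apbap", lambda: IndexedLanguage(
        "apbap", "ab", lambda i: "a" * i[0] + "b" + "a" * i[1], 2,
        _apbap_member))
    add("bach3", lambda: _bach3())
    add("marcus-aba", lambda: FiniteLanguage(
        "marcus-aba", "abcd",
        ["".join((s1, s2, s1)) for s1 in "abcd" for s2 in "abcd"]))
    add("marcus-abb", lambda: FiniteLanguage(
        "marcus-abb", "abcd",
        ["".join((s1, s2, s2)) for s1 in "abcd" for s2 in "abcd"]))
    for size in (2, 6, 12):
        add(f"gomez-{size}", lambda size=size: _gomez(size))
    add("newport-aslin", lambda: FiniteLanguage(
        "newport-aslin", sorted(set("btgdprkuli") | set("1234")),
        [f + x + b for f, b in [("b", "t"), ("g", "d"), ("p", "r"), ("k", "u"), ("l", "i")]
         for x in "1234"]))
    add("saffran", lambda: SaffranLanguage())
    add("reber", lambda: PFSMLanguage(
        "reber", "TSXPV",
        edges={
            0: [("T", 1), ("P", 2)],
            1: [("S", 1), ("X", 3)],
            2: [("T", 2), ("V", 4)],
            3: [("X", 2), ("S", 5)],
            4: [("P", 3), ("V", 5)],
            5: [],
        },
        stop_states=[5]))
    add("berwick-pilato", lambda: PFSMLanguage(
        # Synthetic stand-in for the English-auxiliary machine (figure content
        # unavailable): modal / have / be stages optional, verb obligatory,
        # words recoded to single characters (m, h, b, v).
        "berwick-pilato", "mhbv",
        edges={
            0: [("m", 1), ("h", 2), ("b", 3), ("v", 4)],
            1: [("h", 2), ("b", 3), ("v", 4)],
            2: [("b", 3), ("v", 4)],
            3: [("v", 4)],
            4: [],
        },
        stop_states=[4]))
    add("morgan-newport", lambda: WCFGLanguage(
        # Synthetic stand-in for the Morgan–Newport phrase-structure grammar:
        # three constituents with optional modifiers, the last optional.
        "morgan-newport", "adefcg",
        {
            "S": [(("AP", "BP"), 0.5), (("AP", "BP", "CP"), 0.5)],
            "AP": [(("a",), 0.5), (("a", "d"), 0.5)],
            "BP": [(("e",), 0.5), (("e", "f"), 0.5)],
            "CP": [(("c",), 0.5), (("c", "g"), 0.5)],
        }))
    add("reeder-qaxb", lambda: _reeder())
    add("english", lambda: WCFGLanguage(
        "english", "ndavtp",
        {
            "S": [(("NP", "VP"), 1.0)],
            "NP": [(("n",), 0.35), (("d", "n"), 0.35),
                   (("d", "AP", "n"), 0.2), (("NP", "PP"), 0.1)],
            "AP": [(("a",), 0.7), (("a", "AP"), 0.3)],
            "VP": [(("v",), 0.35), (("v", "NP"), 0.35),
                   (("v", "t", "S"), 0.15), (("VP", "PP"), 0.15)],
            "PP": [(("p", "NP"), 1.0)],
        }))
    return reg


def _is_block_pair(s: str) -> bool:
    i = 0
    while i < len(s) and s[i] == "a":
        i += 1
    return 1 <= i < len(s) and set(s[i:]) == {"b"}


def _apbap_member(s: str) -> bool:
    parts = s.split("b")
    return (
        len(parts) == 2
        and all(len(p) >= 1 and set(p) == {"a"} for p in parts)
    )


def _anbmcndm_member(s: str) -> bool:
    import re

    m = re.fullmatch(r"(a+)(b+)(c+)(d+)", s)
    return bool(m) and len(m.group(1)) == len(m.group(3)) and len(
        m.group(2)
    ) == len(m.group(4))


def _anbmanbmccc_member(s: str) -> bool:
    import re

    m = re.fullmatch(r"(a+)(b+)(a+)(b+)ccc", s)
    return bool(m) and m.group(1) == m.group(3) and m.group(2) == m.group(4)


def _xlenx_member(s: str) -> bool:
    n = len(s)
    root = math.isqrt(n)
    if root * root != n or n == 0:
        return False
    return s == s[:root] * root


def _dyck() -> WCFGLanguage:
    # Nonempty balanced strings; a = open, b = close.
    lang = WCFGLanguage(
        "dyck", "ab",
        {
            "S": [(("a", "T", "b", "T"), 1.0)],
            "T": [(("a", "T", "b", "T"), 1.0 / 3.0), ((), 2.0 / 3.0)],
        })
    def member(s: str) -> bool:
        depth = 0
        for ch in s:
            depth += 1 if ch == "a" else -1 if ch == "b" else -10**9
            if depth < 0:
                return False
        return depth == 0 and len(s) > 0
    lang.membership = member  # type: ignore[method-assign]
    return lang


class _Bach3(TargetLanguage):
    """All strings with equally many a's, b's and c's (nonempty): sampled by
    shuffling aⁿbⁿcⁿ for geometric n."""

    name = "bach3"
    alphabet = ("a", "b", "c")
    stop_prob = DEFAULT_STOP_PROB

    def sample(self, rng: np.random.Generator) -> str:
        n = int(rng.geometric(self.stop_prob))
        chars = list("a" * n + "b" * n + "c" * n)
        rng.shuffle(chars)
        return "".join(chars)

    def top_k(self, k: int) -> TopK:
        found = []
        n = 1
        while len(found) < k:
            perms = sorted(set(itertools.permutations("a" * n + "b" * n + "c" * n)))
            p = math.exp(_geom_logp(n, self.stop_prob)) / len(perms)
            found.extend(("".join(t), p) for t in perms)
            n += 1
        return sorted(found, key=_rank_key)[:k]

    def membership(self, s: str) -> bool:
        return len(s) > 0 and s.count("a") == s.count("b") == s.count("c") == len(s) // 3


def _bach3() -> TargetLanguage:
    return _Bach3()


def _gomez(size: int) -> FiniteLanguage:
    frames = [("b", "t"), ("g", "d"), ("k", "u")]
    middles = "cehijlmnopqr"[:size]
    alphabet = sorted({c for f in frames for c in f} | set(middles))
    return FiniteLanguage(
        f"gomez-{size}", alphabet,
        [l + m + r for l, r in frames for m in middles])


def _reeder() -> FiniteLanguage:
    # QAXB-style category grammar A X B with 3 items per category; a fixed
    # subset of grammatical strings is held out from training.
    A, X, Bc = "asd", "czw", "bgm"
    full = [a + x + b for a in A for x in X for b in Bc]
    held_out = ["acb", "szg", "dwm", "awg", "scm", "dzb"]
    train = [s for s in full if s not in held_out]
    return FiniteLanguage(
        "reeder-qaxb", sorted(set(A + X + Bc)), train, extra_members=held_out)


_REGISTRY = _make_registry()


def language_registry() -> Dict[str, TargetLanguage]:
    """Instantiate the full catalog of named target languages."""
    return {name: fn() for name, fn in _REGISTRY.items()}


def get_language(name: str) -> TargetLanguage:
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown language {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
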