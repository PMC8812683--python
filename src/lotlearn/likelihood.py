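"""Prefix likelihood: P(D | H) under a delete-then-append noise channel.

An observed string d arises from a generated string o by first deleting
characters from the end of o (each deletion with probability δ, stopping
with probability 1−δ) and then appending uniformly random alphabet
characters to the end (each append with probability γ, stopping with
probability 1−γ).  Summing over the number of deletions k gives

    P(d | o) = Σ_{k=0}^{|o|} 1[o[0:|o|−k] is a prefix of d]
               · δ^k (1−δ) · (γ/|Σ|)^{|d|−|o|+k} (1−γ).

The k=|o| term (delete everything, append all of d) always applies, so the
likelihood is never −∞: hypotheses that get prefixes of the data right get
partial credit, which is what makes stochastic search over programs
incremental.  With d = o and no noise the log likelihood is 0.

The channel is normalized up to the truncation of the deletion geometric at
k = |o|: for fixed o, Σ_d P(d|o) = 1 − δ^{|o|+1} over all strings d (the
deficit is negligible at the default δ).

Data likelihood marginalizes the channel over the hypothesis's enumerated
output distribution, i.i.d. across observed tokens.  Unexplored and error
mass contribute nothing, so the value is a lower bound on the exact
marginal likelihood.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from scipy.special import logsumexp

from .evaluator import OutputDistribution
from .lot import EPSILON

__all__ = [
    "NoiseModel",
    "Dataset",
    "LikelihoodError",
    "string_transform_loglik",
    "data_log_likelihood",
]


class LikelihoodError(ValueError):
    """Likelihood undefined (e.g. a hypothesis with no enumerated outcomes)."""


@dataclass(frozen=True)
class NoiseModel:
    """Delete-then-append channel parameters.

    δ (``delete_prob``) and γ (``append_prob``) are per-character
    continuation probabilities; ``alphabet_size`` is |Σ| for the uniform
    choice of appended characters.  Defaults are small (0.01) so the
    channel gives sharp but nonzero partial credit.
    """

    delete_prob: float = 0.01
    append_prob: float = 0.01
    alphabet_size: int = 2

    def __post_init__(self):
        assert 0.0 <= self.delete_prob < 1.0
        assert 0.0 <= self.append_prob < 1.0
        assert self.alphabet_size >= 1


class Dataset:
    """A multiset of observed strings over Σ."""

    def __init__(self, strings: Iterable[str], source_language: Optional[str] = None):
        self.counts: Counter = Counter(strings)
        self.source_language = source_language
        if any(n < 1 for n in self.counts.values()):
            raise ValueError("multiplicities must be >= 1")

    @property
    def n_tokens(self) -> int:
        return sum(self.counts.values())

    @property
    def strings(self) -> List[str]:
        """Distinct observed strings (insertion order)."""
        return list(self.counts)

    def tokens(self) -> Iterable[str]:
        return self.counts.elements()

    def top_k(self, k: int) -> List[str]:
        """The k most frequent strings; ties broken length-then-lexicographic."""
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))
        return [s for s, _ in ranked[:k]]

    def __len__(self) -> int:
        return self.n_tokens

    def __eq__(self, other) -> bool:
        return isinstance(other, Dataset) and self.counts == other.counts

    # -- plain-text serialization (one string per line) --------------------
    # The empty string token cannot be a blank line (blank lines are
    # skipped); it is written as the literal symbol ϵ.

    @classmethod
    def from_file(cls, path, source_language: Optional[str] = None) -> "Dataset":
        strings = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            strings.append("" if line == EPSILON else line)
        return cls(strings, source_language=source_language)

    def to_file(self, path) -> None:
        lines = [s if s else EPSILON for s in self.tokens()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def string_transform_loglik(observed: str, generated: str, nm: NoiseModel) -> float:
    """log P(observed | generated) under the delete-then-append channel."""
    d, o = observed, generated
    log_del = math.log(nm.delete_prob) if nm.delete_prob > 0 else -math.inf
    log_app = (
        math.log(nm.append_prob) - math.log(nm.alphabet_size)
        if nm.append_prob > 0
        else -math.inf
    )
    log_stop_del = math.log1p(-nm.delete_prob)
    log_stop_app = math.log1p(-nm.append_prob)
    # keep = |o| − k characters of o are retained; they must be a prefix of d
    lcp = 0
    for a, b in zip(d, o):
        if a != b:
            break
        lcp += 1
    terms = []
    for keep in range(lcp + 1):
        k = len(o) - keep
        appended = len(d) - keep
        # guard 0·(−∞) = nan when a rate is exactly zero
        term = log_stop_del + log_stop_app
        if k:
            term += k * log_del
        if appended:
            term += appended * log_app
        terms.append(term)
    return float(logsumexp(terms))


from functools import lru_cache

# The same (observed, generated) pairs recur across the thousands of
# hypotheses scored during search; the channel term depends only on the
# pair and the noise parameters, so it is memoized globally.
_cached_transform = lru_cache(maxsize=1 << 20)(string_transform_loglik)


def data_log_likelihood(
    out: OutputDistribution,
    data: Dataset,
    nm: NoiseModel,
    temperature: float = 1.0,
) -> float:
    """log P(D | H) = Σ_d count(d) · log Σ_o P(o|H) P(d|o).

    ``temperature`` divides the total (likelihood tempering for parallel
    tempering chains; the prior is never tempered).
    """
    if not out.outcomes:
        raise LikelihoodError("hypothesis enumerated zero outcomes")
    outcome_items = list(out.outcomes.items())
    log_po = [math.log(p) for _, p in outcome_items]
    total = 0.0
    for d, count in data.counts.items():
        per_token = logsumexp(
            [lp + _cached_transform(d, o, nm) for (o, _), lp in zip(outcome_items, log_po)]
        )
        total += count * per_token
    return float(total) / temperature
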