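"""Posterior-weighted precision/recall, the memorization baseline, learning
curves, and the generalization matrix.

Two reference frames are provided for scoring a posterior set:

* :func:`posterior_precision_recall` — the literal dataset-referenced
  definition: precision is the posterior-weighted fraction of each
  hypothesis's top-k strings that occur anywhere in the observed data;
  recall is the posterior-weighted fraction of the data's top-k strings
  that the hypothesis can generate at all (its enumerated support).

* :func:`language_precision_recall` — the target-language-referenced
  version used for learning curves and the memorization comparison:
  precision checks the hypothesis's top-k strings against language
  membership, recall checks the target's top-k strings against the
  hypothesis's support.  This is the dataset-referenced definition in the
  limit of an arbitrarily large reference sample, and it is the frame in
  which a learner that has found the target program scores F = 1 while a
  memorizer's recall grows only as fast as rare strings are observed.

The memorization baseline treats the observed multiset itself as the
learned distribution and applies the same language-referenced definitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evaluator import DEFAULT_BOUNDS, EvalBounds, OutputDistribution, run_program
from .inference import (
    InferenceConfig,
    PosteriorSet,
    merge_posteriors,
    search_over_factor_counts,
)
from .likelihood import Dataset
from .targets import TargetLanguage, sample_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "EvalError",
    "LearningCurvePoint",
    "posterior_precision_recall",
    "language_precision_recall",
    "memorized_f",
    "learning_curve",
    "generalization_matrix",
    "f_score",
    "DATA_SCHEDULE",
]

#: The standard token schedule for learning curves.
DATA_SCHEDULE = (
    1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000, 5000, 10000, 50000, 100000,
)


class EvalError(ValueError):
    pass


@dataclass(frozen=True)
class EvalConfig:
    """k_top: top-string count (25 by convention; 100 for the English
    grammar); schedule must be strictly increasing."""

    k_top: int = 25
    data_schedule: Tuple[int, ...] = DATA_SCHEDULE
    n_hypotheses: int = 500
    bounds: EvalBounds = DEFAULT_BOUNDS

    def __post_init__(self):
        assert self.k_top >= 1
        assert all(a < b for a, b in zip(self.data_schedule, self.data_schedule[1:]))


def f_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class LearningCurvePoint:
    n_tokens: int
    precision: float
    recall: float
    f: float
    memorized_f: float
    seed: int = 0

    def __post_init__(self):
        for v in (self.precision, self.recall, self.f, self.memorized_f):
            assert -1e-9 <= v <= 1 + 1e-9


def _hypothesis_outputs(
    ps: PosteriorSet, alphabet: Sequence[str], bounds: EvalBounds
) -> List[Tuple[OutputDistribution, float]]:
    out = []
    for h, _, _, w in ps.entries():
        dist = run_program(h, alphabet, bounds=bounds)
        out.append((dist, w))
    return out


def posterior_precision_recall(
    ps: PosteriorSet,
    data: Dataset,
    cfg: EvalConfig = EvalConfig(),
    alphabet: Optional[Sequence[str]] = None,
) -> Tuple[float, float]:
    """Dataset-referenced posterior-weighted precision and recall.

    precision = Σ_h P̂(h|D) · |S_k(h) ∩ S(D)| / |S_k(h)|
    recall    = Σ_h P̂(h|D) · |S(h) ∩ S_k(D)| / |S_k(D)|

    where S_k(h) is the hypothesis's k most probable enumerated strings,
    S(h) its full enumerated support, S(D) the set of observed strings and
    S_k(D) the k most frequent observed strings.
    """
    entries = ps.entries()
    if not entries:
        raise EvalError("empty posterior set")
    if alphabet is None:
        alphabet = _infer_alphabet(data)
    observed = set(data.counts)
    data_top = data.top_k(cfg.k_top)
    precision = 0.0
    recall = 0.0
    for h, _, _, w in entries:
        dist = run_program(h, alphabet, bounds=cfg.bounds)
        top = dist.top_k(cfg.k_top)
        if not top:
            raise EvalError(f"hypothesis {h} enumerated zero strings")
        support = set(dist.outcomes)
        precision += w * sum(1 for s, _ in top if s in observed) / len(top)
        recall += w * sum(1 for s in data_top if s in support) / len(data_top)
    return precision, recall


def language_precision_recall(
    ps: PosteriorSet,
    target: TargetLanguage,
    cfg: EvalConfig = EvalConfig(),
) -> Tuple[float, float]:
    """Target-language-referenced posterior-weighted precision and recall."""
    entries = ps.entries()
    if not entries:
        raise EvalError("empty posterior set")
    target_top = [s for s, _ in target.top_k(cfg.k_top)]
    precision = 0.0
    recall = 0.0
    for h, _, _, w in entries:
        dist = run_program(h, target.alphabet, bounds=cfg.bounds)
        top = dist.top_k(cfg.k_top)
        if not top:
            raise EvalError(f"hypothesis {h} enumerated zero strings")
        support = set(dist.outcomes)
        precision += w * sum(1 for s, _ in top if target.membership(s)) / len(top)
        recall += w * sum(1 for s in target_top if s in support) / len(target_top)
    return precision, recall


def memorized_f(
    data: Dataset, target: TargetLanguage, cfg: EvalConfig = EvalConfig()
) -> float:
    """F score of a learner that memorizes the training multiset.

    The memorizer's top-k strings are the k most frequent observed strings
    and its support is exactly the observed set; the same language-
    referenced precision/recall definitions then apply.
    """
    mem_top = data.top_k(cfg.k_top)
    if not mem_top:
        raise EvalError("empty dataset")
    target_top = [s for s, _ in target.top_k(cfg.k_top)]
    support = set(data.counts)
    precision = sum(1 for s in mem_top if target.membership(s)) / len(mem_top)
    recall = sum(1 for s in target_top if s in support) / len(target_top)
    return f_score(precision, recall)


def _infer_alphabet(data: Dataset) -> Tuple[str, ...]:
    return tuple(sorted({c for s in data.counts for c in s}))


def learning_curve(
    target: TargetLanguage,
    cfg: EvalConfig = EvalConfig(),
    inference_cfg: InferenceConfig = InferenceConfig(),
    factor_counts: Sequence[int] = (1, 2, 3, 4),
    seed: int = 0,
) -> List[LearningCurvePoint]:
    """Sample data, search, and evaluate at each schedule point."""
    points = []
    for i, n_tokens in enumerate(cfg.data_schedule):
        data = sample_dataset(target, n_tokens, seed=seed + 104729 * i)
        sets = search_over_factor_counts(
            data, target.alphabet, inference_cfg, seed=seed + 15485863 * i,
            factor_counts=factor_counts,
        )
        merged = merge_posteriors(list(sets.values()))
        precision, recall = language_precision_recall(merged, target, cfg)
        points.append(
            LearningCurvePoint(
                n_tokens=n_tokens,
                precision=precision,
                recall=recall,
                f=f_score(precision, recall),
                memorized_f=memorized_f(data, target, cfg),
                seed=seed,
            )
        )
        logger.info(
            "%s n=%d: P=%.3f R=%.3f F=%.3f memF=%.3f",
            target.name, n_tokens, precision, recall,
            points[-1].f, points[-1].memorized_f,
        )
    return points


def curve_to_tsv(points: Sequence[LearningCurvePoint]) -> str:
    header = "n_tokens\tprecision\trecall\tF\tmemorized_F\tseed"
    rows = [
        f"{p.n_tokens}\t{p.precision:.6f}\t{p.recall:.6f}\t{p.f:.6f}"
        f"\t{p.memorized_f:.6f}\t{p.seed}"
        for p in points
    ]
    return "\n".join([header] + rows)


def generalization_matrix(
    ps: PosteriorSet,
    data: Dataset,
    probe_strings: Sequence[str],
    alphabet: Sequence[str],
    bounds: EvalBounds = DEFAULT_BOUNDS,
) -> Tuple[List[str], List[List[float]], List[float]]:
    """Per-hypothesis log probabilities of unseen probe strings.

    Probes present in the data are dropped with a warning.  Rows (one per
    hypothesis, sorted by posterior weight descending) with identical
    generalization patterns are deduplicated, keeping the highest-weight
    representative.  Returns (probes, matrix of log P rows, row weights);
    −∞ marks strings a hypothesis cannot generate.
    """
    probes = []
    for s in probe_strings:
        if s in data.counts:
            logger.warning("probe %r occurs in the data; dropped", s)
        else:
            probes.append(s)
    rows: List[List[float]] = []
    weights: List[float] = []
    seen_patterns = set()
    for h, _, _, w in ps.entries():
        dist = run_program(h, alphabet, bounds=bounds)
        row = [
            math.log(dist.outcomes[s]) if s in dist.outcomes else -math.inf
            for s in probes
        ]
        pattern = tuple(np.round(row, 9))
        if pattern in seen_patterns:
            continue
        seen_patterns.add(pattern)
        rows.append(row)
        weights.append(w)
    return probes, rows, weights
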