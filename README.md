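# lotlearn

A domain-general Bayesian program-induction learner for formal languages.
Given only positive example strings, `lotlearn` infers small stochastic
programs — written in a typed combinatory language of string-building
primitives — whose output distributions explain the data. Because
hypotheses are programs rather than grammars of a fixed family, a single
learner covers finite sets, regular patterns, context-free languages such
as aⁿbⁿ and Dyck strings, context-sensitive languages such as aⁿbⁿcⁿ and
the copy language xx, and probabilistic pattern languages from the
artificial-grammar-learning literature.

## The model in one paragraph

A hypothesis H is a list of *factors* F0 … F(n−1), each a typed expression
built from primitives (`pair`, `first`, `rest`, `insert`, `append`,
`empty`, `if`, `and`, `or`, `not`, equality tests, the stochastic coin
`flip(p)` and uniform draw `sample(Σ)`), string/character literals, the
argument variable `x`, and calls to any factor `Fi(·)` or its memoized
variant `Fmi(·)` (memoized calls return the same value every time they are
re-invoked with the same argument within a single execution — this is what
makes reduplication patterns like xx expressible). The last factor, run on
the empty string, defines the hypothesis's output distribution, which is
enumerated exactly by best-first search over execution paths. The prior is
a PCFG over expressions (small programs are exponentially preferred); the
likelihood scores each observed token under a delete-then-append noise
channel applied to the program's outputs, so programs that get prefixes
right receive partial credit. Posterior inference is Metropolis–Hastings
with subtree-regeneration proposals, run as adaptive parallel tempering
across five chains; the search retains the top-scoring distinct programs
as a weighted posterior approximation. Learning is evaluated by
posterior-weighted precision (are the learner's most probable strings in
the target language?) and recall (does the learner generate the target's
most probable strings?).

## Worked example

The program `pair(if(flip(1/3),ϵ,F0(ϵ)),a)` stops with probability 1/3 or
recurses, then appends one `a`; its output law is P(aⁿ) = (2/3)ⁿ⁻¹·1/3:

```python
>>> from lotlearn import parse_hypothesis, run_program
>>> h = parse_hypothesis(["pair(if(flip(1/3),ϵ,F0(ϵ)),a)"], "ab")
>>> dist = run_program(h, "ab")
>>> for s, p in dist.sorted_outcomes()[:5]:
...     print(f"{s!r:10s} {p:.6f}")
'a'        0.333333
'aa'       0.222222
'aaa'      0.148148
'aaaa'     0.098765
'aaaaa'    0.065844
>>> print(f"unexplored mass: {dist.unexplored_mass:.2e}")
unexplored mass: 6.87e-07
```

Learning that program back from 10 sampled tokens (about two minutes on
one CPU):

```python
>>> from lotlearn import get_language, sample_dataset, InferenceConfig
>>> from lotlearn.inference import search_over_factor_counts, merge_posteriors
>>> from lotlearn.evaluation import EvalConfig, language_precision_recall, f_score
>>> target = get_language("an")
>>> data = sample_dataset(target, 10, seed=0)
>>> sorted(data.tokens(), key=len)
['a', 'a', 'a', 'aa', 'aaa', 'aaa', 'aaaa', 'aaaaa', 'aaaaaaa', 'aaaaaaa']
>>> sets = search_over_factor_counts(data, target.alphabet, InferenceConfig(),
...                                  seed=1, factor_counts=(1,))
>>> merged = merge_posteriors(list(sets.values()))
>>> h, _, _, w = merged.entries()[0]
>>> print(f"MAP: {h}  weight={w:.3f}")
MAP: pair(if(flip(2/3),Fm0(a),ϵ),a)  weight=0.026
>>> p, r = language_precision_recall(merged, target, EvalConfig(k_top=25))
>>> print(f"precision={p:.3f} recall={r:.3f} F={f_score(p, r):.3f}")
precision=1.000 recall=0.986 F=0.993
```

The MAP program is not syntactically the generator we started from, but it
is extensionally almost identical — geometric aⁿ with stop probability
1/3 — which is exactly what the precision/recall evaluation measures.

## Command line

```bash
lotlearn languages                                   # list the 33 built-in targets
lotlearn generate --language anbn --n 50 --seed 0 --out data.txt
lotlearn infer    --data data.txt --alphabet ab --n-factors 3 \
                  --steps 2000 --seed 0 --out posterior.jsonl
lotlearn evaluate --posterior posterior.jsonl --data data.txt \
                  --language anbn --k 25 --out eval.json
lotlearn curve    --language an --schedule 1,2,5,10,20,50 --k 25 \
                  --n-factors 1 --seed 0 --out curve.tsv
```

## Reproduction

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/   # ~10 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite includes end-to-end acceptance checks: the analytic output
law above, worked string-manipulation examples, recovery of aⁿ from 10
tokens (majority over 3 seeds), a learner-vs-memorization comparison on
aⁿbⁿcⁿ, and a property suite (exact-vs-Monte-Carlo agreement of the
program semantics, noise-channel normalization, exact posterior recovery
on a restricted hypothesis space, brute-force re-derivation of the scoring
metrics, sampler/membership consistency for every registry language, and
seed determinism). One known-failing check is retained deliberately:
single-CPU desk-scale search does not find an aⁿbⁿcⁿ generator at the
step budgets used here (see `docs/methods.md`, Limitations).

`scripts/acceptance.py` recomputes from scratch the smallest training-set
size at which the learner reaches posterior-weighted F ≥ 0.95 on aⁿ
(majority over 3 seeds per size, schedule 1–50 tokens) and writes it as
JSON. All randomness in tests and scripts derives from fixed or
command-line seeds.

## Package layout

| module | contents |
|---|---|
| `lotlearn.lot` | typed expressions, primitives, parser/printer |
| `lotlearn.prior` | PCFG over expressions, sampling, log-prior |
| `lotlearn.evaluator` | exact enumeration of output distributions; Monte-Carlo oracle |
| `lotlearn.likelihood` | noise channel, datasets, data log-likelihood |
| `lotlearn.inference` | MH over programs, adaptive parallel tempering, posterior sets |
| `lotlearn.targets` | 33 target languages with samplers and membership oracles |
| `lotlearn.evaluation` | precision/recall/F, memorization baseline, learning curves |
| `lotlearn.cli` | the `lotlearn` command |

See `docs/methods.md` for the full model specification, default
parameters, and design rationale.
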