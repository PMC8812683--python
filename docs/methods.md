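# Methods

This document specifies the model implemented by `lotlearn`: the
hypothesis language, the prior, the exact program semantics, the
likelihood, the search procedure, and the evaluation measures, together
with all default parameters and the reasoning behind the main design
choices.

## 1. Hypothesis language

A hypothesis is a tuple of typed expressions ("factors") F0 … F(n−1),
n ∈ {1, …, 4}. Each factor denotes a stochastic function from a string
argument `x` to a value; the *entry factor* is the last one, and the
hypothesis's output distribution is the distribution of the entry factor
applied to the empty string.

Types: `STRING`, `CHAR`, `BOOL`, `STRSET`, `PROB`. A `CHAR` is promoted
to a one-character `STRING` wherever a string is required.

Primitives:

| primitive | type | meaning |
|---|---|---|
| `pair(s, c)` | (STRING, CHAR) → STRING | append character `c` to `s` |
| `first(s)` | STRING → CHAR | first character; error on ϵ |
| `rest(s)` | STRING → STRING | all but the first character; error on ϵ |
| `append(s, t)` | (STRING, STRING) → STRING | concatenation |
| `insert(s, t)` | (STRING, STRING) → STRING | splice `t` into the middle of `s` (after ⌊|s|/2⌋ characters) |
| `empty(s)` | STRING → BOOL | is `s` = ϵ? |
| `equals(s, t)` | (STRING, STRING) → BOOL | string equality |
| `and`, `or`, `not` | BOOL ops | `and`/`or` are short-circuiting |
| `if(b, t, e)` | (BOOL, τ, τ) → τ | lazy conditional, τ ∈ {STRING, CHAR, STRSET, PROB} |
| `flip(p)` | PROB → BOOL | biased coin; `flip()` means `flip(1/2)` |
| `sample(S)` | STRSET → STRING | uniform draw from a finite set |
| `Fi(s)` | STRING → STRING | call factor i |
| `Fmi(s)` | STRING → STRING | memoized call: within one execution, the first call with a given argument fixes the value returned by every later call with that argument |

Terminals: the alphabet characters (CHAR), ϵ (empty STRING), the argument
`x` (STRING), `Σ` (the alphabet as a STRSET), and the probability
literals 1/4, 1/3, 1/2, 2/3, 3/4 (PROB). Any factor may call any factor,
including itself and later ones; mutual and direct recursion are allowed,
and a hypothesis is only proposed/accepted if every factor is reachable
from the entry factor.

Stochastic memoization (`Fmi`) is what separates, e.g., the copy language
from the random-concatenation language: `append(Fm0(ϵ), Fm0(ϵ))` over
F0 = `sample(Σ)` outputs {aa, bb}, while the unmemoized version outputs
all four two-character strings.

Expressions are printed and parsed in a canonical text form (as in all
examples above); the canonical form doubles as the identity used to
deduplicate hypotheses.

## 2. Prior

The prior over a factor is a probabilistic context-free grammar over the
typed productions available at each requested type: at type τ, a fixed
`terminal_mass` (default 0.7) is split uniformly over the terminals of
type τ and the remaining mass uniformly over the non-terminal productions
of type τ. The log-prior of a hypothesis is the sum over factors. This
gives the standard exponential preference for small programs.

The grammar constructor verifies that the branching process of expansion
is subcritical (spectral radius of the expected-offspring matrix < 1), so
prior sampling terminates with probability 1; a depth cap (default 32)
truncates the rare deep samples, and sampling retries until every factor
is reachable. The alphabet may not contain the reserved symbols `x`, `F`,
ϵ, Σ.

## 3. Program semantics: exact enumeration

`run_program` computes the exact output distribution of a hypothesis by
best-first enumeration of execution paths. Each stochastic site (`flip`,
`sample`) is a branch point; a path is a sequence of branch choices with
a log-probability; paths are replayed deterministically from a priority
queue ordered by probability. Factors are compiled once per call into
nested closures, so replaying a path costs one Python frame per
expression node.

Enumeration stops at configurable artifact bounds (`EvalBounds`):

| bound | default | role |
|---|---|---|
| `min_log_prob` | −15 | drop paths less probable than e⁻¹⁵ |
| `max_recursion` | 64 | factor-call depth per path |
| `max_steps` | 1024 | primitive evaluations per path |
| `max_outputs` | 256 | distinct output strings retained |
| `max_paths` | 2000 | paths expanded per program |
| `max_total_steps` | 200000 | total evaluation work per program |
| `max_string_length` | 4096 | length cap for built strings |

Probability mass is conserved and partitioned exactly: every unit of mass
ends up in `outcomes`, `unexplored_mass` (paths left in the frontier when
a cap fires), or `error_mass` (paths that raise, e.g. `first(ϵ)` or
runaway recursion — the length cap exists because doubling constructions
such as `append(x, x)` under recursion otherwise build astronomically
long strings). A larger preset (`ENGLISH_BOUNDS`) is provided for
wide-support languages. `monte_carlo_run` is an independent
forward-sampling oracle used by the tests to validate the enumerator.

## 4. Likelihood

Observed strings are assumed to be program outputs passed through a
delete-then-append channel: delete characters from the end of the output
(each with probability δ, then stop), then append uniform alphabet
characters (each with probability γ, then stop). Summing over the number
of deletions k,

P(d | o) = Σₖ 1[o′ is a prefix of d] · δᵏ(1−δ) · (γ/|Σ|)^{|d|−|o|+k} (1−γ),

where o′ is o with its last k characters removed. The k = |o| term always
contributes, so every (d, o) pair has positive probability: hypotheses
that get prefixes right earn partial credit, which is what makes the
posterior landscape climbable for incremental search. For fixed o the
channel sums to 1 − δ^{|o|+1} over all d (the deletion geometric is
truncated at k = |o|); the deficit is negligible at the defaults
δ = γ = 0.01.

The data log-likelihood marginalizes the channel over the enumerated
output distribution, i.i.d. over tokens. Unexplored and error mass
contribute nothing, so the computed likelihood is a lower bound that is
tight when enumeration is nearly complete. During tempering the
log-likelihood (never the prior) is divided by the chain temperature.

## 5. Search

Proposals regenerate a uniformly chosen subtree: pick a node uniformly
across all factors, resample a fresh subtree at that node's requested
type from the prior, and accept by Metropolis–Hastings with the standard
regeneration Hastings correction. Five chains run at temperatures spaced
exponentially between 1 and 1.2; adjacent-chain swaps are proposed every
100 steps and accepted by the tempered-swap rule, and the ladder adapts
every 2000 steps by a stochastic-approximation update targeting a 0.234
swap-acceptance rate. Scores are cached by canonical printed form. Every
finite-score hypothesis visited by any chain is offered to a deduplicated
top-N posterior set (capacity 500) whose weights are the renormalized
exp(log prior + log likelihood) values — i.e. the standard top-N
approximation to the posterior. The default per-chain step budget is
2000, chosen so that a full single-factor search fits in about a minute
on one CPU; `search_over_factor_counts` runs an independent search per
factor count (default 1–4) from derived seeds and merges the results.

Everything is driven by explicit integer seeds; identical seeds reproduce
runs bit-for-bit.

## 6. Evaluation

For a posterior set with weights w(H), precision and recall are
posterior-weighted set comparisons of top-k string lists (k = 25 by
convention):

* **dataset-referenced** (`posterior_precision_recall`): precision counts
  the hypothesis's top-k strings that occur in the observed data; recall
  counts the data's top-k strings that the hypothesis can generate.
* **language-referenced** (`language_precision_recall`): the same with
  the target language in place of the finite sample — precision uses
  membership, recall uses the target's top-k strings. This is the frame
  used for learning curves and the acceptance checks, because it measures
  generalization rather than fit.

The memorization baseline treats the observed multiset itself as the
learned distribution and is scored in the same language-referenced frame;
its recall can only grow as fast as rare strings happen to be sampled,
which is why it needs on the order of 10⁵ tokens to cover the top 25
strings of aⁿbⁿcⁿ while a program learner generalizes from a handful.
`learning_curve` runs sample → search → evaluate per schedule point
(default schedule 1 … 100000) with per-point derived seeds, and
`generalization_matrix` reports per-hypothesis log-probabilities on
held-out probe strings.

## 7. Target languages

The registry contains 33 languages, each with a sampler and a membership
oracle: finite sets with geometrically skewed sentence probabilities,
regular and center-embedding families (aⁿ, aⁿbⁿ, aⁿbⁿcⁿ, aⁿbⁿcⁿdⁿ,
aⁿb²ⁿ, aⁿbᵐ variants, Dyck, golden-mean, a^{2ⁿ}, counting), copy-type
languages (xx, xxʀ, x^{|x|}), a toy English fragment (a small WCFG over
n, v, d, t, p), and probabilistic pattern families from
artificial-grammar-learning experiments (syllable-stream word
segmentation, ABA/ABB reduplication patterns, nonadjacent-dependency
sets, a finite-state machine topology, and a held-out-string
generalization design whose unsampled grammatical strings are exposed as
`extra_members`). String lengths are geometric with stop probability 1/3
unless a language dictates otherwise. These are synthetic data
generators: the package's empirical scope is formal-language learning,
not corpus modeling.

## 8. Numerical and engineering choices

* All probability arithmetic is in log space with `logsumexp`; channel
  terms guard the 0 · (−∞) case so δ = 0 or γ = 0 are exact.
* The channel term P(d | o) is memoized globally (the same pairs recur
  across thousands of scored hypotheses), and each hypothesis's
  prior+likelihood score is cached by printed form during search.
* The enumerator's compiled closures use an explicit recursion-limit
  raise and convert Python `RecursionError` on pathological
  expression-nesting into error mass rather than crashing the search.
* Expression objects are immutable and hash-cached; proposal and
  enumeration never mutate shared state, which is what makes seed
  determinism exact.

## 9. Limitations

* Enumeration is truncated by the artifact bounds; for programs whose
  mass decays slowly the likelihood is a strict lower bound. Bounds are
  config-exposed and the defaults favor speed.
* Desk-scale budgets learn aⁿ (and comparably simple languages) reliably,
  but single-CPU search at these step budgets does not find an aⁿbⁿcⁿ
  generator; the corresponding acceptance test is left failing rather
  than weakened, and the memorization half of that comparison passes.
* Production weights of the prior are fixed (uniform within
  terminal/non-terminal mass), not learned.
* No cross-run reuse of learned subroutines; each dataset is learned from
  scratch.
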