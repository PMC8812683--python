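"""Typed expression language over language-of-thought string primitives.

Hypotheses are small functional programs built from a fixed first-order
inventory of string, Boolean, and set operations, plus two stochastic
primitives (``flip`` and ``sample``) and (possibly memoized, possibly
recursive) calls to the other factors of the same hypothesis.  Every
expression is typed; the five types are

* ``STRING`` — a finite sequence of alphabet symbols (possibly empty),
* ``CHAR``   — a single alphabet symbol,
* ``BOOL``   — a truth value,
* ``STRSET`` — a finite ordered set of strings,
* ``PROB``   — a probability constant.

A ``CHAR`` is implicitly promoted to a ``STRING`` wherever a ``STRING`` is
required; this is the minimal coercion under which programs such as
``append(sample(Σ),x)`` are well typed.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Optional, Sequence, Tuple

__all__ = [
    "LotType",
    "Primitive",
    "Expression",
    "Hypothesis",
    "ParseError",
    "LotTypeError",
    "AlphabetError",
    "PRIMITIVES",
    "PROB_CONSTANTS",
    "EPSILON",
    "SIGMA",
    "parse_expression",
    "parse_hypothesis",
    "print_expression",
    "type_check",
]

EPSILON = "ϵ"  # ϵ, the empty string symbol
SIGMA = "Σ"  # Σ, the alphabet set symbol

# Probability constants available as PROB terminals.  flip() with no
# argument is accepted as sugar for flip(1/2).
PROB_CONSTANTS: Tuple[Fraction, ...] = (
    Fraction(1, 4),
    Fraction(1, 3),
    Fraction(1, 2),
    Fraction(2, 3),
    Fraction(3, 4),
)


class LotType(enum.Enum):
    STRING = "STRING"
    CHAR = "CHAR"
    BOOL = "BOOL"
    STRSET = "STRSET"
    PROB = "PROB"

    def __repr__(self) -> str:  # terse reprs in error messages
        return self.value


class ParseError(ValueError):
    """Malformed canonical program text."""


class LotTypeError(TypeError):
    """Ill-typed composition of primitives."""


class AlphabetError(ValueError):
    """A character constant outside the configured alphabet."""


@dataclass(frozen=True)
class Primitive:
    """One entry of the primitive inventory.

    ``polymorphic`` marks ``if``, whose branch type ranges over strings,
    sets, and probabilities.  ``stochastic`` marks ``flip`` and ``sample``,
    the only sources of randomness in a program.
    """

    name: str
    arg_types: Tuple[LotType, ...]
    return_type: LotType
    stochastic: bool = False
    polymorphic: bool = False


S, C, B, SET, P = (
    LotType.STRING,
    LotType.CHAR,
    LotType.BOOL,
    LotType.STRSET,
    LotType.PROB,
)

#: The fixed primitive inventory (argument/return types; ``if`` is listed
#: with STRING branches but is checked polymorphically).
PRIMITIVES = {
    p.name: p
    for p in [
        Primitive("pair", (S, C), S),
        Primitive("first", (S,), C),
        Primitive("rest", (S,), S),
        Primitive("insert", (S, S), S),
        Primitive("append", (S, S), S),
        Primitive("flip", (P,), B, stochastic=True),
        Primitive("equals", (S, S), B),
        Primitive("empty", (S,), B),
        Primitive("if", (B, S, S), S, polymorphic=True),
        Primitive("and", (B, B), B),
        Primitive("or", (B, B), B),
        Primitive("not", (B,), B),
        Primitive("singleton", (S,), SET),  # printed with {…} braces
        Primitive("union", (SET, SET), SET),
        Primitive("setminus", (SET, S), SET),
        Primitive("sample", (SET,), S, stochastic=True),
    ]
}

# Branch types permitted for the polymorphic `if`.
IF_BRANCH_TYPES = (S, C, SET, P)

_FACTOR_RE = re.compile(r"^F(m?)(\d+)$")


@dataclass(frozen=True)
class Expression:
    """A node of a program tree.

    ``head`` is a primitive name, a factor reference (``F0``/``Fm1``…), or a
    terminal: a character constant, a probability constant rendered as a
    fraction (``1/3``), ``ϵ``, ``Σ``, or the argument symbol ``x``.
    """

    head: str
    children: Tuple["Expression", ...] = ()

    def __iter__(self) -> Iterator["Expression"]:
        yield self
        for child in self.children:
            yield from child

    @property
    def size(self) -> int:
        return 1 + sum(c.size for c in self.children)

    @property
    def depth(self) -> int:
        return 1 + max((c.depth for c in self.children), default=0)

    def is_factor_call(self) -> bool:
        return _FACTOR_RE.match(self.head) is not None

    def factor_ref(self) -> Optional[Tuple[int, bool]]:
        """Return (index, memoized) for a factor call head, else None.

        Cached on the instance: the interpreter calls this on every visit of
        every node, and the regex match dominated evaluation time otherwise.
        """
        try:
            return self._factor_ref
        except AttributeError:
            pass
        m = _FACTOR_RE.match(self.head)
        ref = None if m is None else (int(m.group(2)), m.group(1) == "m")
        object.__setattr__(self, "_factor_ref", ref)
        return ref

    def __str__(self) -> str:
        return print_expression(self)


@dataclass(frozen=True)
class Hypothesis:
    """An ordered tuple of factor expressions F0 … F_{n−1}.

    Each factor maps STRING→STRING; ``entry_index`` (by convention the last
    factor, matching the worked multi-factor examples where F2 composes F0
    and F1) is the one evaluated at top level with x = ϵ.
    """

    factors: Tuple[Expression, ...]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def entry_index(self) -> int:
        return len(self.factors) - 1

    def called_factors(self, index: int) -> set:
        """Indices of factors referenced anywhere in factor ``index``."""
        out = set()
        for node in self.factors[index]:
            ref = node.factor_ref()
            if ref is not None:
                out.add(ref[0])
        return out

    def all_factors_reachable(self) -> bool:
        """True if every factor is reachable from the entry factor."""
        seen = {self.entry_index}
        stack = [self.entry_index]
        while stack:
            i = stack.pop()
            for j in self.called_factors(i):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_factors

    def __str__(self) -> str:
        return ";".join(print_expression(f) for f in self.factors)

    def __iter__(self) -> Iterator[Expression]:
        return iter(self.factors)


# ---------------------------------------------------------------------------
# Printing
# ---------------------------------------------------------------------------

def _format_prob(q: Fraction) -> str:
    return f"{q.numerator}/{q.denominator}"


PROB_NAMES = {_format_prob(q): float(q) for q in PROB_CONSTANTS}


def print_expression(e: Expression) -> str:
    """Deterministic canonical rendering; inverse of :func:`parse_expression`."""
    if e.head == "singleton":
        return "{" + print_expression(e.children[0]) + "}"
    if not e.children:
        return e.head
    return e.head + "(" + ",".join(print_expression(c) for c in e.children) + ")"


# ---------------------------------------------------------------------------
# Parsing: a small recursive-descent parser over the canonical syntax.
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<punct>[(){},])"
    r"|(?P<frac>\d+/\d+)"
    r"|(?P<name>[A-Za-z][A-Za-z]*\d*)"
    r"|(?P<sym>[^\s(){},])"
    r")"
)


def _tokenize(text: str) -> list:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise ParseError(f"cannot tokenize at position {pos}: {text[pos:]!r}")
        pos = m.end()
        for kind in ("punct", "frac", "name", "sym"):
            val = m.group(kind)
            if val is not None:
                tokens.append(val)
                break
    return tokens


class _Parser:
    def __init__(self, tokens: Sequence[str], alphabet: Sequence[str], n_factors: int):
        self.tokens = list(tokens)
        self.pos = 0
        self.alphabet = tuple(alphabet)
        self.n_factors = n_factors

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of input")
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise ParseError(f"expected {tok!r}, got {got!r}")

    def parse(self) -> Expression:
        e = self.expr()
        if self.peek() is not None:
            raise ParseError(f"trailing input: {self.tokens[self.pos:]}")
        return e

    def expr(self) -> Expression:
        tok = self.next()
        if tok == "{":
            inner = self.expr()
            self.expect("}")
            return Expression("singleton", (inner,))
        if tok in "(){},":
            raise ParseError(f"unexpected {tok!r}")
        # application?
        if self.peek() == "(":
            return self.application(tok)
        return self.terminal(tok)

    def application(self, head: str) -> Expression:
        self.expect("(")
        args = []
        if self.peek() == ")":
            self.next()
        else:
            args.append(self.expr())
            while self.peek() == ",":
                self.next()
                args.append(self.expr())
            self.expect(")")
        fref = _FACTOR_RE.match(head)
        if fref is not None:
            idx = int(fref.group(2))
            if idx >= self.n_factors:
                raise ParseError(
                    f"factor index {idx} out of range for {self.n_factors} factors"
                )
            if len(args) != 1:
                raise ParseError(f"{head} takes one argument, got {len(args)}")
            return Expression(head, tuple(args))
        if head == "flip" and not args:  # flip() is sugar for flip(1/2)
            args = [Expression("1/2")]
        prim = PRIMITIVES.get(head)
        if prim is None:
            raise ParseError(f"unknown function {head!r}")
        if len(args) != len(prim.arg_types):
            raise ParseError(
                f"{head} takes {len(prim.arg_types)} arguments, got {len(args)}"
            )
        return Expression(head, tuple(args))

    def terminal(self, tok: str) -> Expression:
        if tok in (EPSILON, SIGMA, "x"):
            return Expression(tok)
        if tok in PROB_NAMES:
            return Expression(tok)
        if re.fullmatch(r"\d+/\d+", tok):
            raise ParseError(f"probability constant {tok} not in the allowed set")
        if _FACTOR_RE.match(tok):
            raise ParseError(f"factor reference {tok} requires an argument")
        if len(tok) == 1:
            if tok not in self.alphabet:
                raise AlphabetError(f"character {tok!r} not in alphabet {self.alphabet}")
            return Expression(tok)
        raise ParseError(f"unknown symbol {tok!r}")


def parse_expression(
    text: str, alphabet: Sequence[str], n_factors: int = 1
) -> Expression:
    """Parse canonical program text into a well-typed :class:`Expression`.

    Raises :class:`ParseError` for malformed text, :class:`AlphabetError`
    for characters outside Σ, and :class:`LotTypeError` for ill-typed
    composition.
    """
    expr = _Parser(_tokenize(text), alphabet, n_factors).parse()
    type_check(expr)  # raises on type mismatch
    return expr


def parse_hypothesis(texts: Sequence[str], alphabet: Sequence[str]) -> Hypothesis:
    """Parse the factors of a hypothesis (F0 first) from canonical text."""
    n = len(texts)
    factors = tuple(parse_expression(t, alphabet, n_factors=n) for t in texts)
    for f in factors:
        if type_check(f) not in (S, C):
            raise LotTypeError(f"factor {print_expression(f)} is not STRING-typed")
    return Hypothesis(factors)


# ---------------------------------------------------------------------------
# Type checking
# ---------------------------------------------------------------------------

def _terminal_type(head: str) -> Optional[LotType]:
    if head in (EPSILON, "x"):
        return S
    if head == SIGMA:
        return SET
    if head in PROB_NAMES:
        return P
    if len(head) == 1:
        return C
    return None


def _compatible(slot: LotType, t: LotType) -> bool:
    return t == slot or (slot == S and t == C)


def type_check(e: Expression) -> LotType:
    """Return the expression's type, or raise :class:`LotTypeError`.

    ``if`` is checked polymorphically: both branches must share one of the
    branch types (string, char, set, or probability), with CHAR unifying
    with STRING to STRING.
    """
    ref = e.factor_ref()
    if ref is not None:
        t = type_check(e.children[0])
        if not _compatible(S, t):
            raise LotTypeError(f"{e.head} expects STRING, got {t} in {e}")
        return S
    if not e.children:
        t = _terminal_type(e.head)
        if t is None:
            raise LotTypeError(f"unknown terminal {e.head!r}")
        return t
    prim = PRIMITIVES.get(e.head)
    if prim is None:
        raise LotTypeError(f"unknown primitive {e.head!r}")
    child_types = [type_check(c) for c in e.children]
    if prim.polymorphic:  # if(B, X, Y)
        cond, lhs, rhs = child_types
        if cond != B:
            raise LotTypeError(f"if condition must be BOOL, got {cond} in {e}")
        if lhs == rhs:
            branch = lhs
        elif {lhs, rhs} == {S, C}:
            branch = S
        else:
            raise LotTypeError(f"if branches disagree: {lhs} vs {rhs} in {e}")
        if branch not in IF_BRANCH_TYPES:
            raise LotTypeError(f"if branches may not be {branch} in {e}")
        return branch
    for slot, t, child in zip(prim.arg_types, child_types, e.children):
        if not _compatible(slot, t):
            raise LotTypeError(
                f"{e.head} expects {slot}, got {t} for {print_expression(child)}"
            )
    return prim.return_type
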