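"""Formal representation of cognitive profiles and the profile language.

A *profile* is an ordered tuple of finite-valued components (one per
cognitive domain or subdomain); a *profile schema* fixes the component
labels and, for each label, a finite value grid ``(min, max, step)``.
Sentences about profiles are written in a small propositional language
whose atoms compare arithmetic terms over labels (sums and negations)
against numeric constants; negation and conjunction are primitive and
``<=``, ``>=``, ``|``, ``->``, ``<->`` are derived.  The language drives
the belief-revision update of profiles between training sessions.

Concrete ASCII surface syntax::

    wff   := iff
    iff   := imp ('<->' imp)*
    imp   := or  ('->'  or)*          (right-associative)
    or    := and ('|' and)*
    and   := un  ('&' un)*
    un    := '!' un | atom | '(' wff ')'
    atom  := term ('='|'<'|'>'|'<='|'>=') number
    term  := fact (('+'|'-') fact)*   (binary '-' sugars to '+ -')
    fact  := '-' fact | label | '(' term ')'
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence, Union

from .errors import (
    ParseError,
    SchemaError,
    StateSpaceError,
    UnknownLabelError,
)

#: Tolerance for grid membership and atom comparisons.  Grid values are
#: produced by lo + k*step, which is not exact for decimal steps in binary
#: floating point; all equality/strictness checks honour this tolerance.
EPS = 1e-9

#: Default cap on the number of grid profiles model enumeration will visit.
DEFAULT_MODEL_CAP = 200_000


# ---------------------------------------------------------------------------
# Schema and profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSchema:
    """Ordered labels plus a finite value grid per label.

    Parameters
    ----------
    labels
        Unique, non-empty domain/subdomain names, in profile-tuple order.
    grid
        One ``(min, max, step)`` triple per label; ``max - min`` must be an
        integer multiple of ``step``.
    categories
        Optional mapping of a label to an ordered tuple of category names;
        categorical labels are encoded as integers ``0..n-1`` on the grid,
        semantics unchanged.
    """

    labels: tuple[str, ...]
    grid: tuple[tuple[float, float, float], ...]
    categories: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            raise SchemaError("schema must have at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError("schema labels must be unique")
        if len(self.grid) != len(self.labels):
            raise SchemaError("one grid triple required per label")
        for label, (lo, hi, step) in zip(self.labels, self.grid):
            if step <= 0:
                raise SchemaError(f"{label}: grid step must be positive")
            if lo > hi:
                raise SchemaError(f"{label}: grid min exceeds max")
            n = (hi - lo) / step
            if abs(n - round(n)) > 1e-6:
                raise SchemaError(
                    f"{label}: (max - min) must be an integer multiple of step"
                )
        for label in self.categories:
            if label not in self.labels:
                raise SchemaError(f"categorical label {label!r} not in schema")

    @classmethod
    def uniform(
        cls,
        labels: Sequence[str],
        lo: float = 1.0,
        hi: float = 10.0,
        step: float = 0.5,
    ) -> "ProfileSchema":
        """Schema with the same ``(lo, hi, step)`` grid for every label."""
        return cls(tuple(labels), tuple((lo, hi, step) for _ in labels))

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise UnknownLabelError(label) from None

    def grid_for(self, label: str) -> tuple[float, float, float]:
        return self.grid[self.index(label)]

    def values_for(self, label: str) -> tuple[float, ...]:
        """All grid values for ``label``, ascending."""
        lo, hi, step = self.grid_for(label)
        n = int(round((hi - lo) / step))
        return tuple(lo + k * step for k in range(n + 1))

    def grid_size(self, label: str) -> int:
        lo, hi, step = self.grid_for(label)
        return int(round((hi - lo) / step)) + 1

    def on_grid(self, label: str, value: float) -> bool:
        lo, hi, step = self.grid_for(label)
        if value < lo - EPS or value > hi + EPS:
            return False
        k = (value - lo) / step
        return abs(k - round(k)) * step <= EPS

    def snap(self, label: str, value: float) -> float:
        """Nearest grid value (half-up on exact midpoints), clamped."""
        lo, hi, step = self.grid_for(label)
        k = math.floor((value - lo) / step + 0.5)
        return min(max(lo + k * step, lo), hi)

    def encode(self, label: str, category: str) -> int:
        """Grid integer for a categorical label's category name."""
        cats = self.categories.get(label)
        if cats is None or category not in cats:
            raise SchemaError(f"{label!r} has no category {category!r}")
        return cats.index(category)

    def decode(self, label: str, value: float) -> str:
        cats = self.categories.get(label)
        if cats is None:
            raise SchemaError(f"{label!r} is not categorical")
        return cats[int(round(value))]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "grid": {l: list(g) for l, g in zip(self.labels, self.grid)},
            "categories": {l: list(c) for l, c in self.categories.items()},
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ProfileSchema":
        labels = tuple(doc["labels"])
        grid = tuple(tuple(doc["grid"][l]) for l in labels)
        cats = {l: tuple(c) for l, c in doc.get("categories", {}).items()}
        return cls(labels, grid, cats)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ProfileSchema":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class Profile:
    """A point on a schema's grid: one value per label."""

    schema: ProfileSchema
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema.labels):
            raise SchemaError(
                f"profile has {len(self.values)} values for "
                f"{len(self.schema.labels)} labels"
            )
        for label, v in zip(self.schema.labels, self.values):
            if not self.schema.on_grid(label, v):
                raise SchemaError(f"value {v} for {label!r} is off-grid")

    def __getitem__(self, label: str) -> float:
        return self.values[self.schema.index(label)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.schema.labels, self.values))

    def with_value(self, label: str, value: float) -> "Profile":
        vals = list(self.values)
        vals[self.schema.index(label)] = value
        return Profile(self.schema, tuple(vals))

    def to_dict(self) -> dict:
        return {"schema": self.schema.to_dict(), "values": list(self.values)}

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Profile":
        return cls(ProfileSchema.from_dict(doc["schema"]), tuple(doc["values"]))


# ---------------------------------------------------------------------------
# Terms and well-formed formulas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Label:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Neg:
    term: "Term"

    def __str__(self) -> str:
        return f"-{_term_str(self.term)}"


@dataclass(frozen=True)
class Sum:
    left: "Term"
    right: "Term"

    def __str__(self) -> str:
        return f"{self.left} + {_term_str(self.right)}"


Term = Union[Label, Neg, Sum]


def _term_str(t: Term) -> str:
    return f"({t})" if isinstance(t, Sum) else str(t)


COMPARATORS = ("=", "<", ">", "<=", ">=")


@dataclass(frozen=True)
class Atom:
    term: Term
    op: str  # one of COMPARATORS
    const: float

    def __post_init__(self) -> None:
        if self.op not in COMPARATORS:
            raise ValueError(f"bad comparator {self.op!r}")

    def __str__(self) -> str:
        c = self.const
        cs = str(int(c)) if float(c).is_integer() else repr(float(c))
        return f"{self.term} {self.op} {cs}"


@dataclass(frozen=True)
class Not:
    operand: "Wff"

    def __str__(self) -> str:
        return f"!{_wff_str(self.operand)}"


@dataclass(frozen=True)
class And:
    left: "Wff"
    right: "Wff"

    def __str__(self) -> str:
        return f"{_wff_str(self.left)} & {_wff_str(self.right)}"


Wff = Union[Atom, Not, And]


def _wff_str(w: Wff) -> str:
    return f"({w})" if isinstance(w, And) else str(w)


def wff_to_string(wff: Wff) -> str:
    """ASCII surface form; ``parse_wff`` of the result is AST-identical."""
    return str(wff)


def wff_labels(wff: Wff) -> set[str]:
    """Set of label names occurring anywhere in ``wff``."""

    def term_labels(t: Term) -> Iterator[str]:
        if isinstance(t, Label):
            yield t.name
        elif isinstance(t, Neg):
            yield from term_labels(t.term)
        else:
            yield from term_labels(t.left)
            yield from term_labels(t.right)

    if isinstance(wff, Atom):
        return set(term_labels(wff.term))
    if isinstance(wff, Not):
        return wff_labels(wff.operand)
    return wff_labels(wff.left) | wff_labels(wff.right)


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_TWO_CHAR = ("<->", "->", "<=", ">=")
_ONE_CHAR = "()+-!&|=<>"


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Return (kind, value, position) triples; kinds: ID, NUM, OP, END."""
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        matched = False
        for op in _TWO_CHAR:
            if text.startswith(op, i):
                tokens.append(("OP", op, i))
                i += len(op)
                matched = True
                break
        if matched:
            continue
        if c in _ONE_CHAR:
            tokens.append(("OP", c, i))
            i += 1
        elif c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            tokens.append(("NUM", text[i:j], i))
            i = j
        elif c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] in "_."):
                j += 1
            tokens.append(("ID", text[i:j], i))
            i = j
        else:
            raise ParseError(f"unexpected character {c!r}", i)
    tokens.append(("END", "", n))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], schema: ProfileSchema):
        self.tokens = tokens
        self.pos = 0
        self.schema = schema

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.pos]

    def next(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val, at = self.next()
        if val != value:
            raise ParseError(f"expected {value!r}, found {val or 'end of input'!r}", at)

    # precedence-climbing over the derived connectives; all desugar to
    # {Atom, Not, And} except <= and >= which remain atoms with direct
    # semantics (and are semantically equivalent to their !-forms).
    def wff(self) -> Wff:
        return self.iff()

    def iff(self) -> Wff:
        left = self.imp()
        while self.peek()[1] == "<->":
            self.next()
            right = self.imp()
            # a <-> b  ==  (a -> b) & (b -> a)
            left = And(_implies(left, right), _implies(right, left))
        return left

    def imp(self) -> Wff:
        left = self.disj()
        if self.peek()[1] == "->":
            self.next()
            right = self.imp()  # right-associative
            return _implies(left, right)
        return left

    def disj(self) -> Wff:
        left = self.conj()
        while self.peek()[1] == "|":
            self.next()
            right = self.conj()
            left = Not(And(Not(left), Not(right)))
        return left

    def conj(self) -> Wff:
        left = self.unary()
        while self.peek()[1] == "&":
            self.next()
            left = And(left, self.unary())
        return left

    def unary(self) -> Wff:
        kind, val, at = self.peek()
        if val == "!":
            self.next()
            return Not(self.unary())
        if val == "(":
            # Ambiguous: '(' may open a sub-wff or a parenthesized term.
            save = self.pos
            try:
                return self.atom()
            except ParseError:
                self.pos = save
            self.next()
            inner = self.wff()
            self.expect(")")
            return inner
        return self.atom()

    def atom(self) -> Atom:
        term = self.term()
        kind, op, at = self.next()
        if op not in COMPARATORS:
            raise ParseError(
                f"expected a comparator, found {op or 'end of input'!r}", at
            )
        const = self.constant()
        return Atom(term, op, const)

    def constant(self) -> float:
        sign = 1.0
        if self.peek()[1] == "-":
            self.next()
            sign = -1.0
        kind, val, at = self.next()
        if kind != "NUM":
            raise ParseError(f"expected a number, found {val or 'end of input'!r}", at)
        try:
            return sign * float(val)
        except ValueError:
            raise ParseError(f"malformed number {val!r}", at) from None

    def term(self) -> Term:
        left = self.factor()
        while self.peek()[1] in ("+", "-"):
            _, op, _ = self.next()
            right = self.factor()
            left = Sum(left, Neg(right) if op == "-" else right)
        return left

    def factor(self) -> Term:
        kind, val, at = self.next()
        if val == "-":
            return Neg(self.factor())
        if val == "(":
            inner = self.term()
            self.expect(")")
            return inner
        if kind == "ID":
            if val not in self.schema.labels:
                raise UnknownLabelError(val)
            return Label(val)
        raise ParseError(f"expected a label, found {val or 'end of input'!r}", at)


def _implies(a: Wff, b: Wff) -> Wff:
    # a -> b  ==  !(a & !b)
    return Not(And(a, Not(b)))


def parse_wff(text: str, schema: ProfileSchema) -> Wff:
    """Parse a sentence of the profile language against ``schema``.

    Unknown labels raise :class:`UnknownLabelError`; malformed input raises
    :class:`ParseError` with the character position of the offence.
    """
    if not text or not text.strip():
        raise ParseError("empty sentence", 0)
    parser = _Parser(_tokenize(text), schema)
    wff = parser.wff()
    kind, val, at = parser.peek()
    if kind != "END":
        raise ParseError(f"unexpected trailing input {val!r}", at)
    return wff


# ---------------------------------------------------------------------------
# Semantics
# ---------------------------------------------------------------------------

def eval_term(profile: Profile, term: Term) -> float:
    """Value of an arithmetic term at a profile point."""
    if isinstance(term, Label):
        return profile[term.name]
    if isinstance(term, Neg):
        return -eval_term(profile, term.term)
    if isinstance(term, Sum):
        return eval_term(profile, term.left) + eval_term(profile, term.right)
    raise TypeError(f"not a term: {term!r}")


def satisfies(profile: Profile, wff: Wff) -> bool:
    """Classical satisfaction: atoms decided by term value vs constant."""
    if isinstance(wff, Atom):
        v = eval_term(profile, wff.term)
        c = wff.const
        if wff.op == "=":
            return abs(v - c) <= EPS
        if wff.op == "<":
            return v < c - EPS
        if wff.op == ">":
            return v > c + EPS
        if wff.op == "<=":
            return v <= c + EPS
        return v >= c - EPS  # ">="
    if isinstance(wff, Not):
        return not satisfies(profile, wff.operand)
    if isinstance(wff, And):
        return satisfies(profile, wff.left) and satisfies(profile, wff.right)
    raise TypeError(f"not a wff: {wff!r}")


def enumerate_models(
    wff: Wff,
    schema: ProfileSchema,
    cap: int = DEFAULT_MODEL_CAP,
) -> list[Profile]:
    """All grid profiles satisfying ``wff``, in lexicographic value order.

    Raises :class:`StateSpaceError` if the full grid exceeds ``cap`` points.
    """
    size = 1
    for label in schema.labels:
        size *= schema.grid_size(label)
    if size > cap:
        raise StateSpaceError(size, cap)
    axes = [schema.values_for(label) for label in schema.labels]
    out = []
    for combo in itertools.product(*axes):
        p = Profile(schema, combo)
        if satisfies(p, wff):
            out.append(p)
    return out


def profile_distance(
    p: Profile,
    q: Profile,
    weights: Mapping[str, float] | Sequence[float] | None = None,
) -> float:
    """Weighted L1 distance between two profiles on the same schema.

    ``weights`` maps labels to non-negative weights (default: all 1).  With
    strictly positive weights this is a metric and is zero iff ``p == q``.
    """
    if p.schema != q.schema:
        raise SchemaError("profiles live on different schemas")
    if weights is None:
        w = [1.0] * len(p.values)
    elif isinstance(weights, Mapping):
        w = [float(weights.get(l, 1.0)) for l in p.schema.labels]
    else:
        w = [float(x) for x in weights]
        if len(w) != len(p.values):
            raise SchemaError("weight vector length mismatch")
    if any(x < 0 for x in w):
        raise SchemaError("distance weights must be non-negative")
    return float(sum(wi * abs(a - b) for wi, a, b in zip(w, p.values, q.values)))
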