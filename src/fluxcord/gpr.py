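"""Gene-protein-reaction (GPR) rules: parsing and numeric evaluation.

A GPR rule is a boolean expression over gene identifiers in which ``and``
joins subunits of an enzyme complex (all required) and ``or`` joins
isoenzymes (any sufficient).  For scoring, ``and`` maps to the minimum of
the operand values (the least expressed subunit is limiting) and ``or``
maps to their sum (isoforms contribute additively).

Gene tokens are any run of characters excluding whitespace and
parentheses, so both symbolic (``HGNC:1234``, ``GAPDH``) and numeric
(``2597.1``) identifiers are accepted.  ``and``/``or`` keywords are
case-insensitive and bind with standard precedence (``and`` tighter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Union

import numpy as np

__all__ = [
    "GprExpression",
    "GprGene",
    "GprAnd",
    "GprOr",
    "GprSyntaxError",
    "parse_gpr",
    "evaluate_gpr",
]

_MISSING_POLICIES = ("skip", "zero", "undefined")


class GprSyntaxError(ValueError):
    """Raised for malformed GPR strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprGene:
    gene: str

    def to_string(self) -> str:
        return self.gene

    @property
    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})


@dataclass(frozen=True)
class GprAnd:
    children: tuple["GprExpression", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND node requires at least two children")

    def to_string(self) -> str:
        return "(" + " and ".join(c.to_string() for c in self.children) + ")"

    @property
    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes for c in self.children))


@dataclass(frozen=True)
class GprOr:
    children: tuple["GprExpression", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR node requires at least two children")

    def to_string(self) -> str:
        return "(" + " or ".join(c.to_string() for c in self.children) + ")"

    @property
    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes for c in self.children))


GprExpression = Union[GprGene, GprAnd, GprOr]


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            yield ("paren", ch, i)
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            yield ("op", low, i)
        else:
            yield ("gene", word, i)
        i = j


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def parse(self) -> GprExpression:
        if not self.tokens:
            raise GprSyntaxError("empty GPR expression", 0)
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GprSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> GprExpression:
        terms = [self.parse_and()]
        while True:
            tok = self.peek()
            if tok is not None and tok[:2] == ("op", "or"):
                self.next()
                terms.append(self.parse_and())
            else:
                break
        if len(terms) == 1:
            return terms[0]
        # flatten nested ORs so every non-leaf has >= 2 children
        flat: list[GprExpression] = []
        for t in terms:
            flat.extend(t.children) if isinstance(t, GprOr) else flat.append(t)
        return GprOr(tuple(flat))

    def parse_and(self) -> GprExpression:
        factors = [self.parse_factor()]
        while True:
            tok = self.peek()
            if tok is not None and tok[:2] == ("op", "and"):
                self.next()
                factors.append(self.parse_factor())
            else:
                break
        if len(factors) == 1:
            return factors[0]
        flat: list[GprExpression] = []
        for f in factors:
            flat.extend(f.children) if isinstance(f, GprAnd) else flat.append(f)
        return GprAnd(tuple(flat))

    def parse_factor(self) -> GprExpression:
        tok = self.next()
        if tok is None:
            raise GprSyntaxError("dangling operator", len(self.text))
        kind, value, pos = tok
        if kind == "gene":
            return GprGene(value)
        if (kind, value) == ("paren", "("):
            inner = self.parse_or()
            closing = self.next()
            if closing is None or closing[:2] != ("paren", ")"):
                raise GprSyntaxError("unbalanced parentheses", pos)
            return inner
        raise GprSyntaxError(f"unexpected token {value!r}", pos)


def parse_gpr(text: str) -> GprExpression:
    """Parse a GPR rule string into an expression tree.

    Raises :class:`GprSyntaxError` with the character position on
    unbalanced parentheses or dangling operators.
    """
    return _Parser(text).parse()


def evaluate_gpr(
    expr: GprExpression,
    gene_values: Mapping[str, object],
    missing_policy: str = "skip",
):
    """Evaluate a GPR expression against per-gene numeric values.

    AND nodes take the element-wise minimum of their children, OR nodes
    their sum.  Values may be scalars or numpy arrays (evaluated
    element-wise), which lets one score all samples of an expression
    matrix in a single pass.

    ``missing_policy`` controls genes absent from ``gene_values``:

    - ``"skip"`` (default): a missing OR operand is dropped; a missing
      AND operand makes the sub-expression undefined (the limiting
      subunit is unknown).
    - ``"zero"``: missing genes count as zero expression.
    - ``"undefined"``: any missing gene makes the whole score undefined.

    Returns ``None`` when the score is undefined under the chosen policy;
    callers treat such reactions as GPR-less.
    """
    if missing_policy not in _MISSING_POLICIES:
        raise ValueError(
            f"missing_policy must be one of {_MISSING_POLICIES}, got {missing_policy!r}"
        )

    def _eval(node):
        if isinstance(node, GprGene):
            if node.gene in gene_values:
                return gene_values[node.gene]
            return 0.0 if missing_policy == "zero" else None
        values = [_eval(c) for c in node.children]
        if isinstance(node, GprAnd):
            if any(v is None for v in values):
                return None
            return np.minimum.reduce(values)
        # OR node
        if missing_policy == "undefined" and any(v is None for v in values):
            return None
        present = [v for v in values if v is not None]
        if not present:
            return None
        return np.add.reduce(present)

    return _eval(expr)
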