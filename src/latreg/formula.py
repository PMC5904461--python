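"""A small model-formula language for lattice regressions.

Supports ``response ~ x1 + x2 + x1:x2 + I(x1^2) - 1``:

* ``+`` separates terms,
* ``:`` builds interactions,
* ``^k`` (optionally wrapped in ``I(...)``) raises a covariate to a power,
* ``- 1`` suppresses the intercept.

Terms know the symbols and powers they involve, which is what backward
selection needs to respect marginality (a main effect is never dropped
while an interaction or polynomial containing it remains).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True, order=True)
class Term:
    """Product of covariate powers, e.g. ``(('x1', 1), ('x2', 2))``."""

    factors: tuple[tuple[str, int], ...]

    @property
    def label(self) -> str:
        parts = []
        for name, p in self.factors:
            parts.append(name if p == 1 else f"I({name}^{p})")
        return ":".join(parts)

    @property
    def symbols(self) -> frozenset:
        return frozenset(name for name, _ in self.factors)

    @property
    def degree(self) -> int:
        return sum(p for _, p in self.factors)

    def column(self, data) -> np.ndarray:
        col = np.ones(data.n)
        for name, p in self.factors:
            col = col * data.variable(name) ** p
        return col

    def blocks(self, other: "Term") -> bool:
        """True if removing `other` would violate marginality given self."""
        return (
            self != other
            and other.symbols <= self.symbols
            and self.degree > other.degree
        )


_POWER_RE = re.compile(r"^(?:I\()?\s*([A-Za-z_.][\w.]*)\s*\^\s*(\d+)\s*\)?$")
_NAME_RE = re.compile(r"^[A-Za-z_.][\w.]*$")


def _parse_factor(text: str) -> tuple[str, int]:
    text = text.strip()
    m = _POWER_RE.match(text)
    if m:
        return m.group(1), int(m.group(2))
    if _NAME_RE.match(text):
        return text, 1
    raise ValueError(f"cannot parse term factor {text!r}")


def _parse_term(text: str) -> Term:
    factors = tuple(_parse_factor(f) for f in text.split(":"))
    return Term(factors=factors)


@dataclass(frozen=True)
class Formula:
    """Parsed model formula: response, ordered terms, intercept flag."""

    response: str
    terms: tuple[Term, ...]
    intercept: bool = True

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def drop(self, term: Term) -> "Formula":
        return Formula(
            response=self.response,
            terms=tuple(t for t in self.terms if t != term),
            intercept=self.intercept,
        )

    def with_terms(self, terms) -> "Formula":
        return Formula(response=self.response, terms=tuple(terms),
                       intercept=self.intercept)

    def removable(self) -> list[Term]:
        """Terms whose removal respects the model hierarchy."""
        return [
            t for t in self.terms
            if not any(u.blocks(t) for u in self.terms)
        ]

    def design_matrix(self, data) -> tuple[np.ndarray, list[str]]:
        """Model matrix and column names (intercept first when present)."""
        cols, names = [], []
        if self.intercept:
            cols.append(np.ones(data.n))
            names.append("(Intercept)")
        for t in self.terms:
            cols.append(t.column(data))
            names.append(t.label)
        if not cols:
            raise ValueError("empty model: no intercept and no terms")
        return np.column_stack(cols), names

    def __str__(self) -> str:
        rhs = " + ".join(self.labels) if self.terms else "1"
        if not self.intercept:
            rhs += " - 1"
        return f"{self.response} ~ {rhs}"


def parse_formula(text: str) -> Formula:
    """Parse ``'y ~ x1 + x2 + x1:x2 + I(x1^2) - 1'`` into a Formula."""
    if "~" not in text:
        raise ValueError("formula must contain '~'")
    lhs, rhs = text.split("~", 1)
    response = lhs.strip()
    if not _NAME_RE.match(response):
        raise ValueError(f"invalid response name {response!r}")
    intercept = True
    # split on '+' and '-'; a '- 1' (or '-1') drops the intercept
    tokens = re.split(r"(?=[+-])", rhs.replace(" ", ""))
    terms: list[Term] = []
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            continue
        sign = "+"
        if tok[0] in "+-":
            sign, tok = tok[0], tok[1:]
        if tok == "1":
            if sign == "-":
                intercept = False
            continue
        if sign == "-":
            raise ValueError("only '- 1' removal is supported")
        terms.append(_parse_term(tok))
    return Formula(response=response, terms=tuple(terms), intercept=intercept)
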