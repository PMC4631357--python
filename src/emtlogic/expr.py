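"""Boolean rule expressions: parsing, canonical binary trees, evaluation.

Rules are written in a small text grammar::

    expr    := or_expr
    or_expr := and_expr ('|' and_expr)*
    and_expr:= not_expr ('&' not_expr)*
    not_expr:= '!' not_expr | atom
    atom    := NAME | '(' expr ')'

with precedence NOT > AND > OR. N-ary chains (``a & b & c``) are stored as
left-folded binary trees (``(a & b) & c``), which makes the operator-site
indexing used by the robustness analysis well defined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class RuleSyntaxError(ValueError):
    """Raised on malformed rule text; carries line/column information."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {col}" if col is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.col = col


@dataclass(frozen=True)
class Var:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Not:
    child: "Expr"

    def __str__(self) -> str:
        if isinstance(self.child, Var):
            return f"!{self.child}"
        return f"!({self.child})"


@dataclass(frozen=True)
class And:
    left: "Expr"
    right: "Expr"
    op = "AND"

    def __str__(self) -> str:
        return f"{_paren(self.left, And)} & {_paren(self.right, And)}"


@dataclass(frozen=True)
class Or:
    left: "Expr"
    right: "Expr"
    op = "OR"

    def __str__(self) -> str:
        return f"{_paren(self.left, Or)} | {_paren(self.right, Or)}"


Expr = Var | Not | And | Or
_PRECEDENCE = {Or: 1, And: 2, Not: 3, Var: 4}


def _paren(child: Expr, parent_cls: type) -> str:
    # minimal parenthesisation: only when the child binds looser than the
    # parent (Or under And).  Same-class chains print flat, as in published
    # rule tables; reparsing left-folds them back to the canonical tree.
    need = _PRECEDENCE[type(child)] < _PRECEDENCE[parent_cls]
    return f"({child})" if need else str(child)


_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<op>[!&|()]))")


def _tokenize(text: str, line: int) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise RuleSyntaxError(f"unexpected character {text[pos:].strip()[0]!r}", line, pos + 1)
        if m.group("name"):
            tokens.append(("name", m.group("name"), m.start("name") + 1))
        else:
            tokens.append(("op", m.group("op"), m.start("op") + 1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], line: int):
        self.tokens = tokens
        self.i = 0
        self.line = line

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", self.line)
        self.i += 1
        return tok

    def parse(self) -> Expr:
        e = self.or_expr()
        if self.peek() is not None:
            kind, val, col = self.peek()
            raise RuleSyntaxError(f"trailing token {val!r}", self.line, col)
        return e

    def or_expr(self) -> Expr:
        e = self.and_expr()
        while self.peek() is not None and self.peek()[:2] == ("op", "|"):
            self.next()
            e = Or(e, self.and_expr())
        return e

    def and_expr(self) -> Expr:
        e = self.not_expr()
        while self.peek() is not None and self.peek()[:2] == ("op", "&"):
            self.next()
            e = And(e, self.not_expr())
        return e

    def not_expr(self) -> Expr:
        tok = self.peek()
        if tok is not None and tok[:2] == ("op", "!"):
            self.next()
            return Not(self.not_expr())
        return self.atom()

    def atom(self) -> Expr:
        kind, val, col = self.next()
        if kind == "name":
            return Var(val)
        if val == "(":
            e = self.or_expr()
            kind, val, col = self.next()
            if val != ")":
                raise RuleSyntaxError(f"expected ')', got {val!r}", self.line, col)
            return e
        raise RuleSyntaxError(f"unexpected token {val!r}", self.line, col)


def parse_expr(text: str, line: int = 0) -> Expr:
    """Parse a single rule expression into its canonical binary tree."""
    tokens = _tokenize(text, line)
    if not tokens:
        raise RuleSyntaxError("empty expression", line)
    return _Parser(tokens, line).parse()


def variables(expr: Expr) -> set[str]:
    """All node names referenced by the expression."""
    if isinstance(expr, Var):
        return {expr.name}
    if isinstance(expr, Not):
        return variables(expr.child)
    return variables(expr.left) | variables(expr.right)


def evaluate(expr: Expr, state: Mapping[str, int]) -> int:
    if isinstance(expr, Var):
        return int(state[expr.name])
    if isinstance(expr, Not):
        return 1 - evaluate(expr.child, state)
    if isinstance(expr, And):
        return evaluate(expr.left, state) & evaluate(expr.right, state)
    return evaluate(expr.left, state) | evaluate(expr.right, state)


def rename(expr: Expr, mapping: Mapping[str, str]) -> Expr:
    """Rewrite variable names through ``mapping`` (identity for absent keys)."""
    if isinstance(expr, Var):
        return Var(mapping.get(expr.name, expr.name))
    if isinstance(expr, Not):
        return Not(rename(expr.child, mapping))
    cls = type(expr)
    return cls(rename(expr.left, mapping), rename(expr.right, mapping))


def binary_sites(expr: Expr) -> list[And | Or]:
    """Binary (And/Or) operator occurrences in left-to-right written order.

    The traversal is in-order on the canonical binary tree, so for a rule
    written ``a & b | c`` the ``&`` comes before the ``|`` — site indices match
    the order operators appear in the serialised rule.
    """
    out: list[And | Or] = []

    def walk(e: Expr) -> None:
        if isinstance(e, Not):
            walk(e.child)
        elif isinstance(e, (And, Or)):
            walk(e.left)
            out.append(e)
            walk(e.right)

    walk(expr)
    return out


def swap_site(expr: Expr, index: int) -> Expr:
    """Return a copy of ``expr`` with the ``index``-th binary operator flipped
    AND<->OR. Negations and tree shape are untouched."""
    counter = {"i": -1}

    def walk(e: Expr) -> Expr:
        if isinstance(e, Var):
            return e
        if isinstance(e, Not):
            return Not(walk(e.child))
        left = walk(e.left)
        counter["i"] += 1
        here = counter["i"]
        right = walk(e.right)
        if here == index:
            flipped = Or if isinstance(e, And) else And
            return flipped(left, right)
        return type(e)(left, right)

    new = walk(expr)
    if counter["i"] < index:
        raise IndexError(f"operator site {index} out of range ({counter['i'] + 1} sites)")
    return new


def iter_subexpressions(expr: Expr) -> Iterator[Expr]:
    yield expr
    if isinstance(expr, Not):
        yield from iter_subexpressions(expr.child)
    elif isinstance(expr, (And, Or)):
        yield from iter_subexpressions(expr.left)
        yield from iter_subexpressions(expr.right)
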