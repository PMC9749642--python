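"""A small, closed expression language for model equations.

Equations in a model specification are data, not code: they are parsed
into an expression tree over a closed set of builtins (arithmetic,
comparisons, ``IF_THEN_ELSE``, ``MAX``, ``MIN``, and lookup-table
application) and compiled to nested Python closures. No host-language
``eval`` is ever used, so a configuration file can never execute
arbitrary code.

Grammar (lowest to highest precedence)::

    expr    := additive (CMP additive)?        CMP in  <= < >= > == !=
    additive:= term ((+|-) term)*
    term    := unary ((*|/) unary)*
    unary   := - unary | primary
    primary := NUMBER | NAME | NAME '(' expr (',' expr)* ')' | '(' expr ')'

A call ``NAME(...)`` is either one of the builtins ``IF_THEN_ELSE``,
``MAX``, ``MIN`` or the application of a lookup table registered in the
model. Comparisons evaluate to 1.0 (true) or 0.0 (false). Division by an
exactly-zero denominator evaluates to 0.0 and emits
:class:`DivisionByZeroWarning` naming the variable being evaluated, so
degenerate ratios (e.g. occupancy with zero beds) do not abort a run.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

__all__ = [
    "ExpressionError",
    "DivisionByZeroWarning",
    "Node",
    "Num",
    "Var",
    "BinOp",
    "Call",
    "parse",
    "references",
    "compile_expression",
    "BUILTIN_FUNCTIONS",
]

BUILTIN_FUNCTIONS = frozenset({"IF_THEN_ELSE", "MAX", "MIN"})

_CMP_OPS = ("<=", ">=", "==", "!=", "<", ">")


class ExpressionError(ValueError):
    """Raised for a syntactically or semantically malformed equation."""


class DivisionByZeroWarning(RuntimeWarning):
    """Emitted when a division guard returns 0 for a zero denominator."""


# ---------------------------------------------------------------------------
# AST


class Node:
    __slots__ = ()


@dataclass(frozen=True)
class Num(Node):
    value: float


@dataclass(frozen=True)
class Var(Node):
    name: str


@dataclass(frozen=True)
class BinOp(Node):
    op: str
    left: Node
    right: Node


@dataclass(frozen=True)
class Call(Node):
    func: str
    args: tuple[Node, ...]


# ---------------------------------------------------------------------------
# Tokenizer / parser

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|==|!=|[-+*/(),<>])"
    r")"
)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ExpressionError(f"unrecognized token near {rest[:20]!r}")
        tokens.append(m.group().strip())
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: Sequence[str], source: str):
        self.tokens = list(tokens)
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of expression in {self.source!r}")
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise ExpressionError(f"expected {tok!r}, got {got!r} in {self.source!r}")

    def parse(self) -> Node:
        node = self.expr()
        if self.peek() is not None:
            raise ExpressionError(
                f"trailing tokens {self.tokens[self.pos:]} in {self.source!r}"
            )
        return node

    def expr(self) -> Node:
        left = self.additive()
        if self.peek() in _CMP_OPS:
            op = self.next()
            right = self.additive()
            return BinOp(op, left, right)
        return left

    def additive(self) -> Node:
        node = self.term()
        while self.peek() in ("+", "-"):
            op = self.next()
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> Node:
        node = self.unary()
        while self.peek() in ("*", "/"):
            op = self.next()
            node = BinOp(op, node, self.unary())
        return node

    def unary(self) -> Node:
        if self.peek() == "-":
            self.next()
            return BinOp("-", Num(0.0), self.unary())
        if self.peek() == "+":
            self.next()
            return self.unary()
        return self.primary()

    def primary(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.expr()
            self.expect(")")
            return node
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok):
            if self.peek() == "(":
                self.next()
                args = [self.expr()]
                while self.peek() == ",":
                    self.next()
                    args.append(self.expr())
                self.expect(")")
                return Call(tok, tuple(args))
            return Var(tok)
        try:
            return Num(float(tok))
        except ValueError:
            raise ExpressionError(f"unexpected token {tok!r} in {self.source!r}") from None


def parse(text: str) -> Node:
    """Parse an equation string into an expression tree."""
    if not isinstance(text, str) or not text.strip():
        raise ExpressionError("empty equation")
    return _Parser(_tokenize(text), text).parse()


def references(node: Node) -> set[str]:
    """Variable and lookup names referenced by an expression tree.

    Builtin function names are excluded; lookup applications contribute
    the lookup's name (the caller decides whether it resolves to a
    registered table).
    """
    out: set[str] = set()
    _collect(node, out)
    return out


def _collect(node: Node, out: set[str]) -> None:
    if isinstance(node, Var):
        out.add(node.name)
    elif isinstance(node, BinOp):
        _collect(node.left, out)
        _collect(node.right, out)
    elif isinstance(node, Call):
        if node.func not in BUILTIN_FUNCTIONS:
            out.add(node.func)
        for a in node.args:
            _collect(a, out)


# ---------------------------------------------------------------------------
# Compilation to closures

EnvFn = Callable[[dict], float]


def compile_expression(
    node: Node,
    lookups: Mapping[str, Callable[[float], float]],
    context: str = "<expression>",
) -> EnvFn:
    """Compile an expression tree to a function of the evaluation environment.

    ``lookups`` maps lookup names to scalar callables. ``context`` names
    the variable whose equation this is, for diagnostics.
    """
    if isinstance(node, Num):
        v = float(node.value)
        return lambda env: v
    if isinstance(node, Var):
        name = node.name
        return lambda env: env[name]
    if isinstance(node, BinOp):
        lf = compile_expression(node.left, lookups, context)
        rf = compile_expression(node.right, lookups, context)
        op = node.op
        if op == "+":
            return lambda env: lf(env) + rf(env)
        if op == "-":
            return lambda env: lf(env) - rf(env)
        if op == "*":
            return lambda env: lf(env) * rf(env)
        if op == "/":

            def _div(env: dict) -> float:
                denom = rf(env)
                if denom == 0.0:
                    warnings.warn(
                        f"division by zero in equation of {context!r} "
                        f"at TIME={env.get('TIME')}; result set to 0",
                        DivisionByZeroWarning,
                        stacklevel=2,
                    )
                    return 0.0
                return lf(env) / denom

            return _div
        if op == "<=":
            return lambda env: 1.0 if lf(env) <= rf(env) else 0.0
        if op == "<":
            return lambda env: 1.0 if lf(env) < rf(env) else 0.0
        if op == ">=":
            return lambda env: 1.0 if lf(env) >= rf(env) else 0.0
        if op == ">":
            return lambda env: 1.0 if lf(env) > rf(env) else 0.0
        if op == "==":
            return lambda env: 1.0 if lf(env) == rf(env) else 0.0
        if op == "!=":
            return lambda env: 1.0 if lf(env) != rf(env) else 0.0
        raise ExpressionError(f"unknown operator {op!r}")
    if isinstance(node, Call):
        argfs = [compile_expression(a, lookups, context) for a in node.args]
        func = node.func
        if func == "IF_THEN_ELSE":
            if len(argfs) != 3:
                raise ExpressionError(
                    f"IF_THEN_ELSE takes 3 arguments in equation of {context!r}"
                )
            cf, tf, ff = argfs
            return lambda env: tf(env) if cf(env) != 0.0 else ff(env)
        if func == "MAX":
            if len(argfs) < 2:
                raise ExpressionError(f"MAX takes >=2 arguments in {context!r}")
            return lambda env: max(f(env) for f in argfs)
        if func == "MIN":
            if len(argfs) < 2:
                raise ExpressionError(f"MIN takes >=2 arguments in {context!r}")
            return lambda env: min(f(env) for f in argfs)
        if func in lookups:
            if len(argfs) != 1:
                raise ExpressionError(
                    f"lookup {func!r} takes exactly 1 argument in {context!r}"
                )
            table = lookups[func]
            (xf,) = argfs
            return lambda env: table(xf(env))
        raise ExpressionError(
            f"unknown function or lookup {func!r} in equation of {context!r}"
        )
    raise ExpressionError(f"unknown node type {type(node).__name__}")
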