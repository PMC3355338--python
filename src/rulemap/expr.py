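"""Arithmetic expressions for parameters, rates and amounts.

Grammar: ``+ - * / ^`` (``^`` right-associative), unary minus, parentheses,
the functions ``exp``, ``ln``, ``log10``, numeric literals and parameter
references.  Parameters are resolved lazily against an environment of
name -> expression text, with cycle detection.
"""

from __future__ import annotations

import math
import re

from .model import BnglError, Diagnostic

_TOKEN = re.compile(
    r"\s*(?:(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>\*\*|[-+*/^(),]))"
)

_FUNCS = {"exp": math.exp, "ln": math.log, "log10": math.log10,
          "sqrt": math.sqrt}


def tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise BnglError(Diagnostic(
                    "error", f"bad token in expression at {text[pos:]!r}"))
            break
        pos = m.end()
        if m.lastgroup == "num":
            tokens.append(("num", m.group("num")))
        elif m.lastgroup == "name":
            tokens.append(("name", m.group("name")))
        else:
            op = m.group("op")
            tokens.append(("op", "^" if op == "**" else op))
    return tokens


class _Parser:
    def __init__(self, tokens, resolve):
        self.tokens = tokens
        self.pos = 0
        self.resolve = resolve

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise BnglError(Diagnostic("error", "unexpected end of expression"))
        self.pos += 1
        return tok

    def expect(self, op):
        tok = self.take()
        if tok != ("op", op):
            raise BnglError(Diagnostic("error", f"expected {op!r}, got {tok!r}"))

    def expr(self):
        value = self.term()
        while self.peek() in (("op", "+"), ("op", "-")):
            _, op = self.take()
            rhs = self.term()
            value = value + rhs if op == "+" else value - rhs
        return value

    def term(self):
        value = self.unary()
        while self.peek() in (("op", "*"), ("op", "/")):
            _, op = self.take()
            rhs = self.unary()
            value = value * rhs if op == "*" else value / rhs
        return value

    def unary(self):
        if self.peek() == ("op", "-"):
            self.take()
            return -self.unary()
        if self.peek() == ("op", "+"):
            self.take()
            return self.unary()
        return self.power()

    def power(self):
        base = self.atom()
        if self.peek() == ("op", "^"):
            self.take()
            return base ** self.unary()   # right-assoc, binds unary minus
        return base

    def atom(self):
        kind, text = self.take()
        if kind == "num":
            return float(text)
        if kind == "op" and text == "(":
            value = self.expr()
            self.expect(")")
            return value
        if kind == "name":
            if text in _FUNCS:
                self.expect("(")
                arg = self.expr()
                self.expect(")")
                return _FUNCS[text](arg)
            return self.resolve(text)
        raise BnglError(Diagnostic("error", f"unexpected token {text!r}"))


def evaluate(text: str, env: dict[str, str] | None = None,
             overrides: dict[str, float] | None = None) -> float:
    """Evaluate an expression against a parameter environment.

    ``env`` maps parameter names to expression text; ``overrides`` maps
    names directly to numbers and wins over ``env``.  Reference cycles in
    ``env`` raise a diagnostic naming the cycle.
    """
    env = env or {}
    overrides = overrides or {}
    cache: dict[str, float] = {}
    active: list[str] = []

    def resolve(name: str) -> float:
        if name in overrides:
            return float(overrides[name])
        if name in cache:
            return cache[name]
        if name not in env:
            raise BnglError(Diagnostic("error", f"undefined parameter {name!r}"))
        if name in active:
            cycle = " -> ".join(active + [name])
            raise BnglError(Diagnostic(
                "error", f"cyclic parameter definition: {cycle}"))
        active.append(name)
        try:
            value = _eval(env[name], resolve)
        finally:
            active.pop()
        cache[name] = value
        return value

    return _eval(text, resolve)


def _eval(text: str, resolve) -> float:
    parser = _Parser(tokenize(str(text)), resolve)
    value = parser.expr()
    if parser.peek() is not None:
        raise BnglError(Diagnostic(
            "error", f"trailing tokens in expression {text!r}"))
    return float(value)


def evaluate_parameters(parameters: dict[str, str],
                        overrides: dict[str, float] | None = None
                        ) -> dict[str, float]:
    """Resolve every parameter to a number (acyclic dependency check)."""
    overrides = overrides or {}
    out: dict[str, float] = {}
    for name, expr in parameters.items():
        if name in overrides:
            out[name] = float(overrides[name])
        else:
            out[name] = evaluate(expr, parameters, overrides)
    return out
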