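"""Arithmetic expression trees for feature formulas.

The registry stores every proportional/composite formula as a plain-text
expression over analyte tokens, e.g. ``Neu * Plt / Lymph`` or
``0.66 * log10(TBil) - 0.085 * Alb``.  The grammar supports ``+ - * /``,
``^`` (power, right-associative), parentheses, numeric constants, the
functions ``log10``, ``ln``/``loge``, ``sqrt``, and ``ULN(analyte)`` for
upper-limit-of-normal lookups.

Evaluation is vectorized over patients and never raises for data
problems: undefined cells carry a missingness reason code instead
(absent analyte, near-zero denominator, log/sqrt domain violation,
unconfigured ULN).  The near-zero denominator guard is |d| < 1e-12 in
the formula's working units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["Expression", "ExpressionError", "parse_expression", "OK", "ABSENT", "ZERODIV", "DOMAIN", "NO_ULN", "REASON_LABELS"]

# Missingness reason codes, in propagation priority order (lower wins).
OK = 0
ABSENT = 1
ZERODIV = 2
DOMAIN = 3
NO_ULN = 4

REASON_LABELS = {
    OK: "ok",
    ABSENT: "absent-analyte",
    ZERODIV: "zero-denominator",
    DOMAIN: "domain-error",
    NO_ULN: "missing-uln",
}

_DENOM_EPS = 1e-12


class ExpressionError(ValueError):
    """Malformed formula text (a registry bug, not a data problem)."""


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>\*\*|[()+\-*/^,]))"
)

_FUNCS = {"log10", "ln", "loge", "sqrt", "ULN"}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExpressionError(f"cannot tokenize {text!r} at position {pos}")
        pos = m.end()
        if m.group("num") is not None:
            tokens.append(("num", m.group(0).strip()))
        elif m.group("name") is not None:
            tokens.append(("name", m.group("name")))
        else:
            op = m.group("op")
            tokens.append(("op", "^" if op == "**" else op))
    return tokens


@dataclass(frozen=True)
class _Node:
    def analytes(self) -> set[str]:
        raise NotImplementedError


@dataclass(frozen=True)
class _Const(_Node):
    value: float

    def analytes(self) -> set[str]:
        return set()


@dataclass(frozen=True)
class _Analyte(_Node):
    code: str

    def analytes(self) -> set[str]:
        return {self.code}


@dataclass(frozen=True)
class _Uln(_Node):
    code: str

    def analytes(self) -> set[str]:
        return {self.code}


@dataclass(frozen=True)
class _Unary(_Node):
    func: str  # 'neg', 'log10', 'ln', 'sqrt'
    arg: _Node

    def analytes(self) -> set[str]:
        return self.arg.analytes()


@dataclass(frozen=True)
class _Binary(_Node):
    op: str
    left: _Node
    right: _Node

    def analytes(self) -> set[str]:
        return self.left.analytes() | self.right.analytes()


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], text: str) -> None:
        self.tokens = tokens
        self.text = text
        self.pos = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of expression in {self.text!r}")
        self.pos += 1
        return tok

    def expect(self, op: str) -> None:
        tok = self.next()
        if tok != ("op", op):
            raise ExpressionError(f"expected {op!r} in {self.text!r}, got {tok[1]!r}")

    def parse(self) -> _Node:
        node = self.expr()
        if self.peek() is not None:
            raise ExpressionError(f"trailing tokens in {self.text!r}")
        return node

    def expr(self) -> _Node:
        node = self.term()
        while (tok := self.peek()) in (("op", "+"), ("op", "-")):
            self.next()
            node = _Binary(tok[1], node, self.term())
        return node

    def term(self) -> _Node:
        node = self.unary()
        while (tok := self.peek()) in (("op", "*"), ("op", "/")):
            self.next()
            node = _Binary(tok[1], node, self.unary())
        return node

    def unary(self) -> _Node:
        if self.peek() == ("op", "-"):
            self.next()
            return _Unary("neg", self.unary())
        if self.peek() == ("op", "+"):
            self.next()
            return self.unary()
        return self.power()

    def power(self) -> _Node:
        base = self.atom()
        if self.peek() == ("op", "^"):
            self.next()
            return _Binary("^", base, self.unary())  # right-associative
        return base

    def atom(self) -> _Node:
        kind, value = self.next()
        if kind == "num":
            return _Const(float(value))
        if kind == "name":
            if value in _FUNCS:
                self.expect("(")
                if value == "ULN":
                    tok = self.next()
                    if tok[0] != "name":
                        raise ExpressionError(f"ULN() takes an analyte code in {self.text!r}")
                    self.expect(")")
                    return _Uln(tok[1])
                arg = self.expr()
                self.expect(")")
                return _Unary("loge" if value == "ln" else value, arg)
            return _Analyte(value)
        if (kind, value) == ("op", "("):
            node = self.expr()
            self.expect(")")
            return node
        raise ExpressionError(f"unexpected token {value!r} in {self.text!r}")


def _merge(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    return np.where(r1 != OK, r1, r2)


def _flag_new_nan(values: np.ndarray, reasons: np.ndarray, code: int) -> np.ndarray:
    return np.where((reasons == OK) & ~np.isfinite(values), code, reasons)


class Expression:
    """A parsed formula, evaluable on per-analyte value arrays."""

    def __init__(self, text: str) -> None:
        self.text = text
        self._root = _Parser(_tokenize(text), text).parse()
        self.analytes: frozenset[str] = frozenset(self._root.analytes())
        self.uln_analytes: frozenset[str] = frozenset(self._collect_uln(self._root))
        self.has_subtraction: bool = self._has_sub(self._root)

    @staticmethod
    def _collect_uln(node: _Node) -> set[str]:
        if isinstance(node, _Uln):
            return {node.code}
        if isinstance(node, _Unary):
            return Expression._collect_uln(node.arg)
        if isinstance(node, _Binary):
            return Expression._collect_uln(node.left) | Expression._collect_uln(node.right)
        return set()

    @staticmethod
    def _has_sub(node: _Node) -> bool:
        if isinstance(node, _Unary):
            return node.func == "neg" or Expression._has_sub(node.arg)
        if isinstance(node, _Binary):
            return node.op == "-" or Expression._has_sub(node.left) or Expression._has_sub(node.right)
        return False

    def evaluate(
        self,
        values: dict[str, np.ndarray],
        uln: dict[str, float | None] | None = None,
        n: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate on aligned arrays; returns (values, reason codes).

        ``values`` maps analyte code -> float array in the formula's working
        units (NaN = absent).  ``uln`` maps analyte code -> upper limit of
        normal (None or missing key = unconfigured).  Cells with a nonzero
        reason code hold NaN.
        """
        if n is None:
            n = len(next(iter(values.values()))) if values else 1
        out, reasons = self._eval(self._root, values, uln or {}, n)
        out = np.where(reasons == OK, out, np.nan)
        return out, reasons

    def _eval(
        self, node: _Node, values: dict[str, np.ndarray], uln: dict[str, float | None], n: int
    ) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(node, _Const):
            return np.full(n, node.value), np.zeros(n, dtype=np.int8)
        if isinstance(node, _Analyte):
            v = np.asarray(values.get(node.code, np.full(n, np.nan)), dtype=float)
            reasons = np.where(np.isfinite(v), OK, ABSENT).astype(np.int8)
            return v, reasons
        if isinstance(node, _Uln):
            limit = uln.get(node.code)
            if limit is None:
                return np.full(n, np.nan), np.full(n, NO_ULN, dtype=np.int8)
            return np.full(n, float(limit)), np.zeros(n, dtype=np.int8)
        if isinstance(node, _Unary):
            v, r = self._eval(node.arg, values, uln, n)
            with np.errstate(all="ignore"):
                if node.func == "neg":
                    return -v, r
                if node.func == "log10":
                    out = np.where(v > 0, np.log10(np.where(v > 0, v, 1.0)), np.nan)
                elif node.func == "loge":
                    out = np.where(v > 0, np.log(np.where(v > 0, v, 1.0)), np.nan)
                else:  # sqrt
                    out = np.where(v >= 0, np.sqrt(np.abs(v)), np.nan)
            return out, _flag_new_nan(out, r, DOMAIN)
        assert isinstance(node, _Binary)
        lv, lr = self._eval(node.left, values, uln, n)
        rv, rr = self._eval(node.right, values, uln, n)
        r = _merge(lr, rr)
        with np.errstate(all="ignore"):
            if node.op == "+":
                out = lv + rv
            elif node.op == "-":
                out = lv - rv
            elif node.op == "*":
                out = lv * rv
            elif node.op == "/":
                near_zero = np.abs(rv) < _DENOM_EPS
                out = np.where(near_zero, np.nan, lv / np.where(near_zero, 1.0, rv))
                r = np.where((r == OK) & near_zero, ZERODIV, r)
            else:  # '^'
                out = np.power(lv, rv)
        return out, _flag_new_nan(out, r, DOMAIN)


def parse_expression(text: str) -> Expression:
    return Expression(text)
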