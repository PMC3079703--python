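"""Boolean expression language for transition conditions.

Conditions on scenario transitions are small infix expressions over
declared scenario variables and the invoking node's last operator result
(``result.found``, ``result.count``, ``result.value_num``), with
comparisons, ``and``/``or``/``not`` and parentheses::

    result.found and fracture_age >= 65
    result.count > 3 or not bmd_done

Logic is three-valued: a comparison touching a null is null, ``and``/``or``
follow Kleene semantics, and the engine treats a null condition as not
taken (it falls through to OTHERWISE and is logged).  Missing data in a
chart must never silently count as evidence either way.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any, Mapping, Optional

__all__ = ["Expression", "ExpressionError", "parse_expression"]


class ExpressionError(ValueError):
    pass


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<num>-?\d+(?:\.\d+)?)
      | (?P<str>'[^']*'|"[^"]*")
      | (?P<op><=|>=|==|!=|<|>)
      | (?P<lpar>\()
      | (?P<rpar>\))
      | (?P<name>[A-Za-z_][A-Za-z_0-9]*(?:\.[A-Za-z_][A-Za-z_0-9]*)*)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "true", "false", "null"}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ExpressionError(f"cannot tokenize near: {text[pos:]!r}")
            break
        pos = m.end()
        kind = m.lastgroup
        val = m.group(kind)
        if kind == "name" and val.lower() in _KEYWORDS:
            tokens.append((val.lower(), val))
        else:
            tokens.append((kind, val))
    return tokens


# AST nodes are plain tuples: ("lit", v) ("ref", path) ("cmp", op, l, r)
# ("and"/"or", l, r) ("not", x)


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], text: str):
        self.tokens = tokens
        self.i = 0
        self.text = text

    def peek(self) -> Optional[str]:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def take(self, kind: str) -> str:
        if self.peek() != kind:
            raise ExpressionError(f"expected {kind} in {self.text!r}")
        val = self.tokens[self.i][1]
        self.i += 1
        return val

    def parse(self) -> tuple:
        node = self.or_expr()
        if self.i != len(self.tokens):
            raise ExpressionError(f"trailing tokens in {self.text!r}")
        return node

    def or_expr(self) -> tuple:
        node = self.and_expr()
        while self.peek() == "or":
            self.take("or")
            node = ("or", node, self.and_expr())
        return node

    def and_expr(self) -> tuple:
        node = self.not_expr()
        while self.peek() == "and":
            self.take("and")
            node = ("and", node, self.not_expr())
        return node

    def not_expr(self) -> tuple:
        if self.peek() == "not":
            self.take("not")
            return ("not", self.not_expr())
        return self.comparison()

    def comparison(self) -> tuple:
        left = self.atom()
        if self.peek() == "op":
            op = self.take("op")
            return ("cmp", op, left, self.atom())
        return left

    def atom(self) -> tuple:
        kind = self.peek()
        if kind == "num":
            return ("lit", float(self.take("num")))
        if kind == "str":
            return ("lit", self.take("str")[1:-1])
        if kind == "true":
            self.take("true")
            return ("lit", True)
        if kind == "false":
            self.take("false")
            return ("lit", False)
        if kind == "null":
            self.take("null")
            return ("lit", None)
        if kind == "lpar":
            self.take("lpar")
            node = self.or_expr()
            self.take("rpar")
            return node
        if kind == "name":
            return ("ref", self.take("name"))
        raise ExpressionError(f"unexpected end of expression in {self.text!r}")


_CMP = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def _resolve(path: str, env: Mapping[str, Any]) -> Any:
    head, *rest = path.split(".")
    if head not in env:
        raise ExpressionError(f"unknown name: {head!r}")
    obj: Any = env[head]
    for attr in rest:
        if obj is None:
            return None
        if isinstance(obj, Mapping):
            obj = obj.get(attr)
        elif hasattr(obj, attr):
            obj = getattr(obj, attr)
        else:
            raise ExpressionError(f"cannot resolve {path!r}: no field {attr!r}")
    return obj


def _eval(node: tuple, env: Mapping[str, Any]) -> Any:
    op = node[0]
    if op == "lit":
        return node[1]
    if op == "ref":
        return _resolve(node[1], env)
    if op == "not":
        v = _truth(_eval(node[1], env))
        return None if v is None else not v
    if op == "and":
        l = _truth(_eval(node[1], env))
        if l is False:
            return False
        r = _truth(_eval(node[2], env))
        if r is False:
            return False
        return None if (l is None or r is None) else True
    if op == "or":
        l = _truth(_eval(node[1], env))
        if l is True:
            return True
        r = _truth(_eval(node[2], env))
        if r is True:
            return True
        return None if (l is None or r is None) else False
    if op == "cmp":
        _, cmp_op, ln, rn = node
        a, b = _eval(ln, env), _eval(rn, env)
        # a syntactic null literal makes ==/!= a null *test* (like SQL's
        # IS NULL); otherwise any null operand poisons the comparison
        if cmp_op in ("==", "!=") and (ln == ("lit", None) or rn == ("lit", None)):
            eq = (a is None) == (b is None)
            return eq if cmp_op == "==" else not eq
        if a is None or b is None:
            return None
        try:
            return _CMP[cmp_op](a, b)
        except TypeError as exc:
            raise ExpressionError(f"incomparable operands for {cmp_op}: {a!r}, {b!r}") from exc
    raise AssertionError(op)


def _truth(v: Any) -> Optional[bool]:
    if v is None:
        return None
    return bool(v)


@dataclass(frozen=True)
class Expression:
    """A parsed condition; ``evaluate`` returns True, False or None."""

    text: str
    ast: tuple

    def evaluate(self, env: Mapping[str, Any]) -> Optional[bool]:
        return _truth(_eval(self.ast, env))

    def names(self) -> set[str]:
        """Top-level names referenced (for validation against declarations)."""
        out: set[str] = set()

        def walk(node: tuple) -> None:
            if node[0] == "ref":
                out.add(node[1].split(".")[0])
            elif node[0] in ("and", "or", "not"):
                for child in node[1:]:
                    walk(child)
            elif node[0] == "cmp":
                walk(node[2])
                walk(node[3])

        walk(self.ast)
        return out


def parse_expression(text: str) -> Expression:
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    return Expression(text, _Parser(tokens, text).parse())
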