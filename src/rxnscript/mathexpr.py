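"""Expression trees for kinetic laws, triggers, rules and initializers.

The tree is shared by every stage of the pipeline: the text parser builds
it, the serializer renders it back to canonical text, and the SBML bridge
converts it to and from content MathML.  Three csymbols are understood —
simulation ``time``, ``rateOf`` (the instantaneous time derivative of a
model symbol, SBML L3V2 Core) and the distribution draw functions of the
SBML Distributions package (``normal``, ``uniform``, ``lognormal``, ...).

Seeded numeric evaluation is provided for expressions whose symbols are
bound; distribution draws consume a :class:`numpy.random.Generator` so
Monte-Carlo experiments are reproducible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
from lxml import etree

__all__ = [
    "MathNode", "Num", "Sym", "Time", "Bin", "Neg", "Cmp", "BoolOp", "Call",
    "ExpressionError", "EvaluationError", "MathMLError",
    "parse_expression", "render_expression", "to_mathml", "from_mathml",
    "evaluate", "free_symbols", "fmt_number",
    "DRAW_FUNCTIONS", "STD_FUNCTIONS",
    "MATHML_NS", "TIME_URL", "RATEOF_URL", "DISTRIB_URL_PREFIX",
]

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"
RATEOF_URL = "http://www.sbml.org/sbml/symbols/rateOf"
DISTRIB_URL_PREFIX = "http://www.sbml.org/sbml/symbols/distrib/"

# name -> arity; every one maps 1:1 onto a content-MathML element so the
# MathML round trip stays structurally exact.
STD_FUNCTIONS: dict[str, int] = {
    "sin": 1, "cos": 1, "tan": 1, "exp": 1, "ln": 1, "log10": 1,
    "sqrt": 1, "abs": 1, "floor": 1, "ceiling": 1,
}

# Distributions-package draw functions with their two-parameter call forms
# (normal takes a standard deviation, lognormal the log-scale mu/sigma).
DRAW_FUNCTIONS: dict[str, int] = {
    "normal": 2, "uniform": 2, "lognormal": 2, "exponential": 1,
    "gamma": 2, "poisson": 1, "binomial": 2,
}

RESERVED_WORDS = {"time", "and", "or", "not"}


class ExpressionError(ValueError):
    """Syntax error in expression text; carries a 1-based column."""

    def __init__(self, message: str, column: int = 1):
        super().__init__(message)
        self.column = column


class EvaluationError(ValueError):
    pass


class MathMLError(ValueError):
    """Raised for MathML outside the supported content subset."""


# ---------------------------------------------------------------------------
# Node variants
# ---------------------------------------------------------------------------

class MathNode:
    """Base class for expression-tree nodes (all variants are frozen)."""

    __slots__ = ()


@dataclass(frozen=True)
class Num(MathNode):
    value: float

    def __post_init__(self):
        object.__setattr__(self, "value", float(self.value))


@dataclass(frozen=True)
class Sym(MathNode):
    id: str


@dataclass(frozen=True)
class Time(MathNode):
    """The simulation-time csymbol; ``time`` is a reserved word."""


@dataclass(frozen=True)
class Bin(MathNode):
    op: str  # + - * / ^
    left: MathNode
    right: MathNode


@dataclass(frozen=True)
class Neg(MathNode):
    child: MathNode


@dataclass(frozen=True)
class Cmp(MathNode):
    op: str  # < <= > >= == !=
    left: MathNode
    right: MathNode


@dataclass(frozen=True)
class BoolOp(MathNode):
    op: str  # and | or | not
    children: tuple[MathNode, ...]

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))


@dataclass(frozen=True)
class Call(MathNode):
    name: str
    args: tuple[MathNode, ...]

    def __post_init__(self):
        object.__setattr__(self, "args", tuple(self.args))


def free_symbols(node: MathNode) -> set[str]:
    """All identifiers referenced anywhere in the tree (rateOf args included)."""
    out: set[str] = set()
    for n in walk(node):
        if isinstance(n, Sym):
            out.add(n.id)
    return out


def walk(node: MathNode) -> Iterator[MathNode]:
    yield node
    if isinstance(node, Bin) or isinstance(node, Cmp):
        yield from walk(node.left)
        yield from walk(node.right)
    elif isinstance(node, Neg):
        yield from walk(node.child)
    elif isinstance(node, BoolOp):
        for c in node.children:
            yield from walk(c)
    elif isinstance(node, Call):
        for a in node.args:
            yield from walk(a)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<id>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><=|>=|==|!=|&&|\|\||[-+*/^<>(),!])
  | (?P<ws>\s+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    # the Unicode minus occasionally survives copy-paste from typeset text
    text = text.replace("−", "-")
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ExpressionError(f"unexpected character {text[pos]!r}", pos + 1)
        if m.lastgroup != "ws":
            kind = m.lastgroup
            val = m.group()
            if kind == "op":
                val = {"&&": "and", "||": "or", "!": "not"}.get(val, val)
                if val in ("and", "or", "not"):
                    kind = "id"
            tokens.append((kind, val, pos + 1))
        pos = m.end()
    tokens.append(("eof", "", len(text) + 1))
    return tokens


class _ExprParser:
    """Recursive-descent expression parser with conventional precedence."""

    def __init__(self, tokens: list[tuple[str, str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val, col = self.next()
        if val != value:
            raise ExpressionError(f"expected {value!r}, found {val or 'end of input'!r}", col)

    def parse(self) -> MathNode:
        node = self.parse_or()
        kind, val, col = self.peek()
        if kind != "eof":
            raise ExpressionError(f"unexpected token {val!r}", col)
        return node

    def parse_or(self) -> MathNode:
        node = self.parse_and()
        while self.peek()[1] == "or":
            self.next()
            node = BoolOp("or", (node, self.parse_and()))
        return node

    def parse_and(self) -> MathNode:
        node = self.parse_not()
        while self.peek()[1] == "and":
            self.next()
            node = BoolOp("and", (node, self.parse_not()))
        return node

    def parse_not(self) -> MathNode:
        if self.peek()[1] == "not":
            self.next()
            return BoolOp("not", (self.parse_not(),))
        return self.parse_cmp()

    def parse_cmp(self) -> MathNode:
        node = self.parse_add()
        if self.peek()[1] in ("<", "<=", ">", ">=", "==", "!="):
            _, op, col = self.next()
            right = self.parse_add()
            node = Cmp(op, node, right)
            if self.peek()[1] in ("<", "<=", ">", ">=", "==", "!="):
                raise ExpressionError(
                    "chained comparisons are not allowed inside expressions",
                    self.peek()[2])
        return node

    def parse_add(self) -> MathNode:
        node = self.parse_mul()
        while self.peek()[1] in ("+", "-"):
            _, op, _ = self.next()
            node = Bin(op, node, self.parse_mul())
        return node

    def parse_mul(self) -> MathNode:
        node = self.parse_unary()
        while self.peek()[1] in ("*", "/"):
            _, op, _ = self.next()
            node = Bin(op, node, self.parse_unary())
        return node

    def parse_unary(self) -> MathNode:
        if self.peek()[1] == "-":
            self.next()
            return Neg(self.parse_unary())
        if self.peek()[1] == "+":
            self.next()
            return self.parse_unary()
        return self.parse_pow()

    def parse_pow(self) -> MathNode:
        base = self.parse_atom()
        if self.peek()[1] == "^":
            self.next()
            # right-associative; exponent may carry a unary minus
            return Bin("^", base, self.parse_unary())
        return base

    def parse_atom(self) -> MathNode:
        kind, val, col = self.next()
        if kind == "num":
            return Num(float(val))
        if kind == "id":
            if val in ("and", "or", "not"):
                raise ExpressionError(f"unexpected keyword {val!r}", col)
            if self.peek()[1] == "(":
                return self.parse_call(val, col)
            if val == "time":
                return Time()
            return Sym(val)
        if val == "(":
            node = self.parse_or()
            self.expect(")")
            return node
        raise ExpressionError(f"unexpected token {val or 'end of input'!r}", col)

    def parse_call(self, name: str, col: int) -> MathNode:
        self.expect("(")
        args: list[MathNode] = []
        if self.peek()[1] != ")":
            args.append(self.parse_or())
            while self.peek()[1] == ",":
                self.next()
                args.append(self.parse_or())
        self.expect(")")
        if name == "rateOf":
            if len(args) != 1 or not isinstance(args[0], Sym):
                raise ExpressionError(
                    "rateOf takes exactly one argument and it must be an identifier", col)
        elif name in STD_FUNCTIONS:
            if len(args) != STD_FUNCTIONS[name]:
                raise ExpressionError(
                    f"{name} expects {STD_FUNCTIONS[name]} argument(s), got {len(args)}", col)
        elif name in DRAW_FUNCTIONS:
            if len(args) != DRAW_FUNCTIONS[name]:
                raise ExpressionError(
                    f"{name} expects {DRAW_FUNCTIONS[name]} argument(s), got {len(args)}", col)
        else:
            raise ExpressionError(f"unknown function {name!r}", col)
        return Call(name, tuple(args))


def parse_expression(text: str) -> MathNode:
    """Parse expression text into a tree.

    Precedence, loosest to tightest: ``or``, ``and``, ``not``, comparisons,
    ``+ -``, ``* /``, unary minus, ``^`` (right-associative).  ``&&``, ``||``
    and ``!`` are accepted as alternate spellings of the boolean connectives.
    """
    if not text or not text.strip():
        raise ExpressionError("empty expression")
    return _ExprParser(_tokenize(text)).parse()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def fmt_number(value: float) -> str:
    """Shortest round-trip decimal; integral values print without a point."""
    value = float(value)
    if value != value or value in (float("inf"), float("-inf")):
        return {float("inf"): "inf", float("-inf"): "-inf"}.get(value, "nan")
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(value)


_PREC = {"or": 1, "and": 2, "not": 3, "cmp": 4, "+": 5, "-": 5,
         "*": 6, "/": 6, "neg": 7, "^": 8, "atom": 10}


def _prec(node: MathNode) -> int:
    if isinstance(node, Bin):
        return _PREC[node.op]
    if isinstance(node, Neg):
        return _PREC["neg"]
    if isinstance(node, Cmp):
        return _PREC["cmp"]
    if isinstance(node, BoolOp):
        return _PREC[node.op]
    return _PREC["atom"]


def render_expression(node: MathNode) -> str:
    """Canonical text with minimal parentheses; inverse of parse_expression."""
    return _render(node)


def _paren(child: MathNode, limit: int, strict: bool) -> str:
    text = _render(child)
    p = _prec(child)
    if p < limit or (strict and p == limit):
        return f"({text})"
    return text


def _render(node: MathNode) -> str:
    if isinstance(node, Num):
        return fmt_number(node.value)
    if isinstance(node, Sym):
        return node.id
    if isinstance(node, Time):
        return "time"
    if isinstance(node, Bin):
        p = _PREC[node.op]
        if node.op == "^":
            # right-assoc: parenthesize a left child of equal precedence
            return f"{_paren(node.left, p, strict=True)}^{_paren(node.right, p, strict=False)}"
        left = _paren(node.left, p, strict=False)
        # all four are left-associative: an equal-precedence right child
        # must keep its parentheses for the reparse to rebuild the same tree
        right = _paren(node.right, p, strict=True)
        if node.op in ("+", "-"):
            return f"{left} {node.op} {right}"
        return f"{left}{node.op}{right}"
    if isinstance(node, Neg):
        return f"-{_paren(node.child, _PREC['neg'], strict=False)}"
    if isinstance(node, Cmp):
        p = _PREC["cmp"]
        return f"{_paren(node.left, p, strict=True)} {node.op} {_paren(node.right, p, strict=True)}"
    if isinstance(node, BoolOp):
        p = _PREC[node.op]
        if node.op == "not":
            return f"not {_paren(node.children[0], p, strict=False)}"
        parts = [_paren(node.children[0], p, strict=False)]
        for c in node.children[1:]:
            parts.append(_paren(c, p, strict=True))
        return f" {node.op} ".join(parts)
    if isinstance(node, Call):
        return f"{node.name}({', '.join(_render(a) for a in node.args)})"
    raise TypeError(f"not a MathNode: {node!r}")


# ---------------------------------------------------------------------------
# Content MathML
# ---------------------------------------------------------------------------

_M = "{%s}" % MATHML_NS

_OP_ELEMENT = {"+": "plus", "-": "minus", "*": "times", "/": "divide", "^": "power"}
_CMP_ELEMENT = {"<": "lt", "<=": "leq", ">": "gt", ">=": "geq", "==": "eq", "!=": "neq"}
_ELEMENT_OP = {v: k for k, v in _OP_ELEMENT.items()}
_ELEMENT_CMP = {v: k for k, v in _CMP_ELEMENT.items()}
_FN_ELEMENT = {"sin": "sin", "cos": "cos", "tan": "tan", "exp": "exp", "ln": "ln",
               "log10": "log", "sqrt": "root", "abs": "abs", "floor": "floor",
               "ceiling": "ceiling"}
_ELEMENT_FN = {v: k for k, v in _FN_ELEMENT.items()}


def math_element(node: MathNode) -> etree._Element:
    """Build the ``<math>`` wrapper element for embedding in SBML."""
    root = etree.Element(_M + "math", nsmap={None: MATHML_NS})
    root.append(_to_ml(node))
    return root


def to_mathml(node: MathNode) -> str:
    """Serialize a tree to a content-MathML ``<math>`` fragment (text)."""
    return etree.tostring(math_element(node), encoding="unicode")


def _cn(value: float) -> etree._Element:
    el = etree.Element(_M + "cn")
    if value == int(value) and abs(value) < 1e16:
        el.set("type", "integer")
        el.text = str(int(value))
    else:
        el.text = repr(value)
    return el


def _csymbol(name: str, url: str) -> etree._Element:
    el = etree.Element(_M + "csymbol")
    el.set("encoding", "text")
    el.set("definitionURL", url)
    el.text = name
    return el


def _apply(*children: etree._Element) -> etree._Element:
    el = etree.Element(_M + "apply")
    for c in children:
        el.append(c)
    return el


def _to_ml(node: MathNode) -> etree._Element:
    if isinstance(node, Num):
        return _cn(node.value)
    if isinstance(node, Sym):
        el = etree.Element(_M + "ci")
        el.text = node.id
        return el
    if isinstance(node, Time):
        return _csymbol("time", TIME_URL)
    if isinstance(node, Bin):
        return _apply(etree.Element(_M + _OP_ELEMENT[node.op]),
                      _to_ml(node.left), _to_ml(node.right))
    if isinstance(node, Neg):
        return _apply(etree.Element(_M + "minus"), _to_ml(node.child))
    if isinstance(node, Cmp):
        return _apply(etree.Element(_M + _CMP_ELEMENT[node.op]),
                      _to_ml(node.left), _to_ml(node.right))
    if isinstance(node, BoolOp):
        return _apply(etree.Element(_M + node.op), *[_to_ml(c) for c in node.children])
    if isinstance(node, Call):
        if node.name == "rateOf":
            head = _csymbol("rateOf", RATEOF_URL)
        elif node.name in DRAW_FUNCTIONS:
            head = _csymbol(node.name, DISTRIB_URL_PREFIX + node.name)
        elif node.name in STD_FUNCTIONS:
            head = etree.Element(_M + _FN_ELEMENT[node.name])
        else:
            raise MathMLError(f"unsupported function {node.name!r}")
        return _apply(head, *[_to_ml(a) for a in node.args])
    raise MathMLError(f"unsupported node variant {type(node).__name__}")


def from_mathml(xml: str | etree._Element) -> MathNode:
    """Parse a content-MathML fragment back into a tree.

    Inverse of :func:`to_mathml` on the supported node set.  Elements outside
    that set (``piecewise``, ``lambda``, ...) raise :class:`MathMLError`
    naming the offending element.
    """
    if isinstance(xml, (str, bytes)):
        try:
            el = etree.fromstring(xml.encode() if isinstance(xml, str) else xml)
        except etree.XMLSyntaxError as exc:
            raise MathMLError(f"not well-formed XML: {exc}") from exc
    else:
        el = xml
    if _local(el) == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise MathMLError("math element must contain exactly one child")
        el = children[0]
    return _from_ml(el)


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _from_ml(el: etree._Element) -> MathNode:
    name = _local(el)
    if name == "cn":
        ctype = el.get("type", "real")
        if ctype not in ("real", "integer", "double"):
            raise MathMLError(f"unsupported cn type {ctype!r}")
        value = float((el.text or "").strip())
        if value < 0:
            return Neg(Num(-value))
        return Num(value)
    if name == "ci":
        return Sym((el.text or "").strip())
    if name == "csymbol":
        url = el.get("definitionURL", "")
        if url == TIME_URL:
            return Time()
        raise MathMLError(f"unsupported bare csymbol {url!r}")
    if name != "apply":
        raise MathMLError(f"unsupported MathML element {name!r}")

    children = [c for c in el if isinstance(c.tag, str)]
    if not children:
        raise MathMLError("empty apply element")
    head, args = children[0], [_from_ml(c) for c in children[1:]]
    hname = _local(head)
    if hname == "csymbol":
        url = head.get("definitionURL", "")
        if url == RATEOF_URL:
            if len(args) != 1 or not isinstance(args[0], Sym):
                raise MathMLError("rateOf requires a single ci argument")
            return Call("rateOf", tuple(args))
        if url.startswith(DISTRIB_URL_PREFIX):
            fname = url[len(DISTRIB_URL_PREFIX):]
            if fname not in DRAW_FUNCTIONS or len(args) != DRAW_FUNCTIONS[fname]:
                raise MathMLError(f"unsupported distribution csymbol {url!r}")
            return Call(fname, tuple(args))
        raise MathMLError(f"unsupported csymbol {url!r}")
    if hname == "minus":
        if len(args) == 1:
            return Neg(args[0])
        if len(args) == 2:
            return Bin("-", args[0], args[1])
        raise MathMLError("minus takes one or two operands")
    if hname in _ELEMENT_OP:
        if hname in ("plus", "times") and len(args) > 2:
            node = Bin(_ELEMENT_OP[hname], args[0], args[1])
            for extra in args[2:]:
                node = Bin(_ELEMENT_OP[hname], node, extra)
            return node
        if len(args) != 2:
            raise MathMLError(f"{hname} takes two operands")
        return Bin(_ELEMENT_OP[hname], args[0], args[1])
    if hname in _ELEMENT_CMP:
        if len(args) != 2:
            raise MathMLError(f"{hname} takes two operands")
        return Cmp(_ELEMENT_CMP[hname], args[0], args[1])
    if hname in ("and", "or"):
        if len(args) < 2:
            raise MathMLError(f"{hname} takes at least two operands")
        node = BoolOp(hname, (args[0], args[1]))
        for extra in args[2:]:
            node = BoolOp(hname, (node, extra))
        return node
    if hname == "not":
        if len(args) != 1:
            raise MathMLError("not takes one operand")
        return BoolOp("not", tuple(args))
    if hname in ("log", "root"):
        # only the qualifier-free default forms are bijective with our names
        if len(args) != 1:
            raise MathMLError(f"{hname} with qualifiers is unsupported")
        return Call(_ELEMENT_FN[hname], tuple(args))
    if hname in _ELEMENT_FN:
        if len(args) != 1:
            raise MathMLError(f"{hname} takes one operand")
        return Call(_ELEMENT_FN[hname], tuple(args))
    raise MathMLError(f"unsupported MathML element {hname!r}")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _draw(name: str, params: list[float], rng: np.random.Generator) -> float:
    if name == "normal":
        mean, sd = params
        if sd <= 0:
            raise EvaluationError("normal: sd must be > 0")
        return float(rng.normal(mean, sd))
    if name == "uniform":
        lo, hi = params
        if lo >= hi:
            raise EvaluationError("uniform: lower bound must be < upper bound")
        return float(rng.uniform(lo, hi))
    if name == "lognormal":
        mu, sigma = params
        if sigma <= 0:
            raise EvaluationError("lognormal: sigma must be > 0")
        return float(rng.lognormal(mu, sigma))
    if name == "exponential":
        (rate,) = params
        if rate <= 0:
            raise EvaluationError("exponential: rate must be > 0")
        return float(rng.exponential(1.0 / rate))
    if name == "gamma":
        shape, scale = params
        if shape <= 0 or scale <= 0:
            raise EvaluationError("gamma: shape and scale must be > 0")
        return float(rng.gamma(shape, scale))
    if name == "poisson":
        (rate,) = params
        if rate < 0:
            raise EvaluationError("poisson: rate must be >= 0")
        return float(rng.poisson(rate))
    if name == "binomial":
        n, p = params
        if n < 0 or n != int(n) or not 0.0 <= p <= 1.0:
            raise EvaluationError("binomial: need integer n >= 0 and p in [0,1]")
        return float(rng.binomial(int(n), p))
    raise EvaluationError(f"unknown draw function {name!r}")


_FN_EVAL = {
    "sin": math.sin, "cos": math.cos, "tan": math.tan, "exp": math.exp,
    "ln": math.log, "log10": math.log10, "sqrt": math.sqrt, "abs": abs,
    "floor": math.floor, "ceiling": math.ceil,
}


def evaluate(node: MathNode,
             bindings: Mapping[str, float] | None = None,
             rng: np.random.Generator | None = None) -> float:
    """Numerically evaluate a tree.

    All symbols must be bound; ``rateOf`` and ``time`` have no value outside
    a simulator and are rejected.  Comparisons and boolean connectives
    return 1.0/0.0.  Draw functions consume ``rng`` (required when present),
    so identical seed and bindings give identical results.
    """
    bindings = bindings or {}
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Sym):
        if node.id not in bindings:
            raise EvaluationError(f"unbound symbol {node.id!r}")
        return float(bindings[node.id])
    if isinstance(node, Time):
        raise EvaluationError("time has no value outside a simulation")
    if isinstance(node, Bin):
        a = evaluate(node.left, bindings, rng)
        b = evaluate(node.right, bindings, rng)
        if node.op == "+":
            return a + b
        if node.op == "-":
            return a - b
        if node.op == "*":
            return a * b
        if node.op == "/":
            if b == 0:
                raise EvaluationError("division by zero")
            return a / b
        return float(a ** b)
    if isinstance(node, Neg):
        return -evaluate(node.child, bindings, rng)
    if isinstance(node, Cmp):
        a = evaluate(node.left, bindings, rng)
        b = evaluate(node.right, bindings, rng)
        ok = {"<": a < b, "<=": a <= b, ">": a > b, ">=": a >= b,
              "==": a == b, "!=": a != b}[node.op]
        return 1.0 if ok else 0.0
    if isinstance(node, BoolOp):
        vals = [evaluate(c, bindings, rng) != 0.0 for c in node.children]
        if node.op == "and":
            return 1.0 if all(vals) else 0.0
        if node.op == "or":
            return 1.0 if any(vals) else 0.0
        return 0.0 if vals[0] else 1.0
    if isinstance(node, Call):
        if node.name == "rateOf":
            raise EvaluationError("rateOf has no value outside a simulation")
        args = [evaluate(a, bindings, rng) for a in node.args]
        if node.name in _FN_EVAL:
            try:
                return float(_FN_EVAL[node.name](*args))
            except ValueError as exc:
                raise EvaluationError(f"{node.name}: {exc}") from exc
        if node.name in DRAW_FUNCTIONS:
            if rng is None:
                raise EvaluationError(
                    f"{node.name} draw requires a random generator")
            return _draw(node.name, args, rng)
        raise EvaluationError(f"unknown function {node.name!r}")
    raise EvaluationError(f"cannot evaluate {type(node).__name__}")
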