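"""Expression trees: parsing, rendering, MathML, seeded evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rxnscript.mathexpr import (
    Bin, BoolOp, Call, Cmp, EvaluationError, ExpressionError, MathMLError,
    Neg, Num, Sym, Time, evaluate, from_mathml, parse_expression,
    render_expression, to_mathml, DRAW_FUNCTIONS, RATEOF_URL, TIME_URL,
)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("k1*S1", Bin("*", Sym("k1"), Sym("S1"))),
    ("time > 2 and x < 1",
     BoolOp("and", (Cmp(">", Time(), Num(2)), Cmp("<", Sym("x"), Num(1))))),
    ("time > 2 && x < 1",
     BoolOp("and", (Cmp(">", Time(), Num(2)), Cmp("<", Sym("x"), Num(1))))),
    ("2^3^2", Bin("^", Num(2), Bin("^", Num(3), Num(2)))),       # right-assoc
    ("a - b - c", Bin("-", Bin("-", Sym("a"), Sym("b")), Sym("c"))),
    ("-a^2", Neg(Bin("^", Sym("a"), Num(2)))),
    ("uniform(0, 2)", Call("uniform", (Num(0), Num(2)))),
    ("rateOf(G)", Call("rateOf", (Sym("G"),))),
    ("not x > 1", BoolOp("not", (Cmp(">", Sym("x"), Num(1)),))),
])
def test_parse_structure(text, expected):
    assert parse_expression(text) == expected


@pytest.mark.parametrize("bad", [
    "", "   ", "(a + b", "a +* b", "rateOf(3+4)", "rateOf(a, b)",
    "uniform(1)", "frobnicate(1)", "a < b < c", "1 2", "a @ b",
])
def test_parse_errors(bad):
    with pytest.raises(ExpressionError):
        parse_expression(bad)


def test_syntax_error_carries_column():
    with pytest.raises(ExpressionError) as exc:
        parse_expression("a + )")
    assert exc.value.column == 5


# ---------------------------------------------------------------------------
# Rendering (canonical text, minimal parentheses)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text", [
    "k1*S1", "a + b*c", "(a + b)*c", "a - (b - c)", "2^3^2", "(2^3)^2",
    "-a^2", "(-a)^2", "a/b/c", "a/(b/c)", "not (a and b)", "time > 2 and x < 1",
    "rateOf(G)", "uniform(0, 2)", "lognormal(0.1, 0.25)", "0",
])
def test_render_parse_identity(text):
    tree = parse_expression(text)
    assert parse_expression(render_expression(tree)) == tree


def test_render_examples():
    assert render_expression(Bin("*", Sym("k1"), Sym("S1"))) == "k1*S1"
    assert render_expression(Num(0)) == "0"
    assert render_expression(Num(2.5)) == "2.5"


# tree generator for the structural round-trip properties
_ids = st.sampled_from(["a", "b", "k1", "S1", "x_long"])
_leaves = st.one_of(
    st.floats(min_value=0, max_value=1e6, allow_nan=False).map(Num),
    _ids.map(Sym),
    st.just(Time()),
)


def _compose(children):
    arith = st.builds(Bin, st.sampled_from(["+", "-", "*", "/", "^"]),
                      children, children)
    return st.one_of(
        arith,
        st.builds(Neg, children),
        st.builds(Cmp, st.sampled_from(["<", "<=", ">", ">=", "==", "!="]),
                  children, children),
        st.builds(lambda op, a, b: BoolOp(op, (a, b)),
                  st.sampled_from(["and", "or"]), children, children),
        st.builds(lambda a: BoolOp("not", (a,)), children),
        st.builds(lambda f, a: Call(f, (a,)),
                  st.sampled_from(["sin", "exp", "ln", "sqrt", "abs"]), children),
        st.builds(lambda f, a, b: Call(f, (a, b)),
                  st.sampled_from(["uniform", "normal", "lognormal"]),
                  children, children),
        _ids.map(lambda i: Call("rateOf", (Sym(i),))),
    )


_trees = st.recursive(_leaves, _compose, max_leaves=25)


@settings(max_examples=200, derandomize=True)
@given(_trees)
def test_text_roundtrip_property(tree):
    """parse(render(t)) is structurally identical to t."""
    assert parse_expression(render_expression(tree)) == tree


@settings(max_examples=200, derandomize=True)
@given(_trees)
def test_mathml_roundtrip_property(tree):
    """from_mathml(to_mathml(t)) is structurally identical to t."""
    assert from_mathml(to_mathml(tree)) == tree


# ---------------------------------------------------------------------------
# Content MathML specifics
# ---------------------------------------------------------------------------

def test_mathml_csymbol_urls():
    xml = to_mathml(Call("rateOf", (Sym("G"),)))
    assert RATEOF_URL in xml and ">rateOf<" in xml and ">G<" in xml
    xml = to_mathml(Time())
    assert TIME_URL in xml
    xml = to_mathml(Call("uniform", (Num(0), Num(1))))
    assert "http://www.sbml.org/sbml/symbols/distrib/uniform" in xml


def test_mathml_number_forms():
    assert 'type="integer">10<' in to_mathml(Num(10))
    tree = from_mathml('<math xmlns="http://www.w3.org/1998/Math/MathML">'
                       '<cn>-2.5</cn></math>')
    assert tree == Neg(Num(2.5))


def test_mathml_unsupported_element_named():
    xml = ('<math xmlns="http://www.w3.org/1998/Math/MathML">'
           '<piecewise><piece><cn>1</cn></piece></piecewise></math>')
    with pytest.raises(MathMLError, match="piecewise"):
        from_mathml(xml)


def test_mathml_nary_fold():
    xml = ('<math xmlns="http://www.w3.org/1998/Math/MathML"><apply><plus/>'
           '<cn>1</cn><cn>2</cn><cn>3</cn></apply></math>')
    assert from_mathml(xml) == Bin("+", Bin("+", Num(1), Num(2)), Num(3))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def test_evaluate_arithmetic_and_logic():
    assert evaluate(parse_expression("2^3 - 1")) == 7
    assert evaluate(parse_expression("3 < 4")) == 1.0
    assert evaluate(parse_expression("3 >= 4 or 1 == 1")) == 1.0
    assert evaluate(parse_expression("not 0")) == 1.0
    assert evaluate(parse_expression("k*2"), {"k": 3.5}) == 7.0


def test_evaluate_errors():
    with pytest.raises(EvaluationError, match="unbound"):
        evaluate(parse_expression("k*2"))
    with pytest.raises(EvaluationError, match="time"):
        evaluate(parse_expression("time + 1"))
    with pytest.raises(EvaluationError, match="rateOf"):
        evaluate(parse_expression("rateOf(G)"), {"G": 1.0})
    rng = np.random.default_rng(0)
    with pytest.raises(EvaluationError, match="uniform"):
        evaluate(parse_expression("uniform(2, 1)"), {}, rng)
    with pytest.raises(EvaluationError, match="normal"):
        evaluate(parse_expression("normal(0, 0)"), {}, rng)
    with pytest.raises(EvaluationError, match="requires a random"):
        evaluate(parse_expression("uniform(0, 1)"))


def test_evaluate_purity():
    tree = parse_expression("normal(5, 2) + uniform(0, 1)")
    a = [evaluate(tree, {}, np.random.default_rng(42)) for _ in range(5)]
    b = [evaluate(tree, {}, np.random.default_rng(42)) for _ in range(5)]
    assert a == b


_MOMENTS = {
    # expression -> (mean, variance)
    "uniform(0, 2)": (1.0, 4 / 12),
    "normal(5, 2)": (5.0, 4.0),
    "lognormal(0.1, 0.25)": (math.exp(0.1 + 0.25 ** 2 / 2),
                             (math.exp(0.25 ** 2) - 1)
                             * math.exp(2 * 0.1 + 0.25 ** 2)),
    "exponential(4)": (0.25, 1 / 16),
    "gamma(3, 2)": (6.0, 12.0),
    "poisson(3)": (3.0, 3.0),
    "binomial(10, 0.3)": (3.0, 2.1),
}


@pytest.mark.parametrize("expr", sorted(_MOMENTS))
def test_draw_moments(expr):
    """Seeded sample means match closed forms within four standard errors."""
    mean, var = _MOMENTS[expr]
    n = 20_000
    rng = np.random.default_rng(7)
    tree = parse_expression(expr)
    samples = np.array([evaluate(tree, {}, rng) for _ in range(n)])
    se = math.sqrt(var / n)
    assert abs(samples.mean() - mean) < 4 * se
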