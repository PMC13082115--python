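"""Statement parsing: every clause kind, diagnostics, fuzz crash-freedom."""

import random

import pytest

from rxnscript import SymbolKind, parse_document, semantic_equal
from rxnscript.mathexpr import Call, Cmp, Num, Sym, Time, BoolOp
from rxnscript.parser import (
    ClauseError, parse_annotation_clause, parse_dot_clause,
    parse_event_clause, parse_inequality_clause, parse_objective_clause,
    parse_reaction_clause, parse_rule_or_init_clause,
)
from rxnscript.model import Constraint, FluxBoundSet, Model, declare


def _errors(diags):
    return [d for d in diags if d.severity == "error"]


# ---------------------------------------------------------------------------
# parse_document basics
# ---------------------------------------------------------------------------

def test_single_reaction_implicit_declarations():
    m, diags = parse_document("S1 -> S2; k1*S1")
    assert not diags
    assert len(m.reactions) == 1
    kinds = {k: v.kind for k, v in m.symbols.items()}
    assert kinds["S1"] is SymbolKind.SPECIES
    assert kinds["S2"] is SymbolKind.SPECIES
    assert kinds["k1"] is SymbolKind.PARAMETER


def test_empty_input_is_empty_valid_model():
    m, diags = parse_document("")
    assert not diags and not m.symbols and m.id == "__main"


def test_typographic_arrow_accepted():
    m, diags = parse_document("S1 −> S2; k1*S1")
    assert not diags and len(m.reactions) == 1


def test_model_header_and_end():
    m, diags = parse_document("model cascade\nA -> B\nend")
    assert m.id == "cascade" and not _errors(diags)


def test_comments_are_stripped():
    text = ("// leading comment\nS1 -> S2; k1*S1  // rate\n"
            "/* block\n   spanning lines */\nk1 = 2\n"
            'S1 is "http://example.org/a//b"\n')
    m, diags = parse_document(text)
    assert not _errors(diags)
    assert m.symbols["k1"].initial_value == 2
    assert m.annotations[0].uri == "http://example.org/a//b"  # // kept in string


def test_diagnostics_carry_line_numbers():
    _, diags = parse_document("A -> B\n\n???bad???\n")
    errs = _errors(diags)
    assert errs and errs[0].line == 3


# ---------------------------------------------------------------------------
# reaction clauses
# ---------------------------------------------------------------------------

def test_reaction_clause_rate_law():
    rxn = parse_reaction_clause("S1 -> S2; k1*S1")
    assert [r.species_id for r in rxn.reactants] == ["S1"]
    assert [r.species_id for r in rxn.products] == ["S2"]
    assert rxn.kinetic_math == parse_rate("k1*S1")


def parse_rate(text):
    from rxnscript.mathexpr import parse_expression
    return parse_expression(text)


def test_reaction_named_stoichiometry():
    m = Model()
    rxn = parse_reaction_clause("J0: n L -> RL; k*L^n", m)
    assert rxn.id == "J0"
    assert rxn.reactants[0].stoichiometry_id == "n"
    assert m.symbols["n"].kind is SymbolKind.STOICHIOMETRY
    assert m.symbols["L"].kind is SymbolKind.SPECIES


def test_reaction_numeric_coefficients():
    rxn = parse_reaction_clause("2 A + B -> 3 C")
    assert [r.stoichiometry for r in rxn.reactants] == [2.0, 1.0]
    assert [r.stoichiometry for r in rxn.products] == [3.0]


def test_reaction_exchange_sides_may_be_empty_but_not_both():
    rxn = parse_reaction_clause("S1 -> ; k*S1")
    assert rxn.reactants and not rxn.products
    with pytest.raises(ClauseError):
        parse_reaction_clause(" -> ")


def test_reaction_two_coefficients_in_a_row():
    with pytest.raises(ClauseError, match="two coefficients"):
        parse_reaction_clause("2 3 A -> B")


def test_auto_reaction_ids_in_declaration_order():
    m, _ = parse_document("A -> B\nB -> C")
    assert [r.id for r in m.reactions] == ["_J0", "_J1"]


# ---------------------------------------------------------------------------
# event clauses
# ---------------------------------------------------------------------------

def test_event_basic():
    m = Model()
    ev = parse_event_clause("E0: at time > 3: k4 = 10", m)
    assert ev.id == "E0"
    assert ev.trigger == Cmp(">", Time(), Num(3))
    assert ev.assignments == [("k4", Num(10))]
    assert ev.persistent and ev.initial_value_trigger \
        and ev.use_values_from_trigger_time


def test_event_with_priority_draw():
    ev = parse_event_clause(
        "E1: at time > 2 and x < 1, priority = uniform(0,2): x = 5")
    assert ev.priority == Call("uniform", (Num(0), Num(2)))
    assert ev.trigger == BoolOp("and", (Cmp(">", Time(), Num(2)),
                                        Cmp("<", Sym("x"), Num(1))))
    assert ev.assignments == [("x", Num(5))]


def test_event_auto_id_and_errors():
    ev = parse_event_clause("at x > 0: y = 1")
    assert ev.id == "_E0"
    with pytest.raises(ClauseError):
        parse_event_clause("at x > 0")       # missing ':' and assignments
    with pytest.raises(ClauseError):
        parse_event_clause("E0: at x > 0: ")  # empty assignment list


# ---------------------------------------------------------------------------
# rules and initializations
# ---------------------------------------------------------------------------

def test_algebraic_rule():
    m = Model()
    rule = parse_rule_or_init_clause("A1: 0 = S1 + S2", m)
    assert rule.rule_kind == "algebraic" and rule.id == "A1"
    assert m.symbols["A1"].kind is SymbolKind.RULE


def test_initialization_number_vs_draw():
    m = Model()
    parse_rule_or_init_clause("S1 = 10", m)
    assert m.symbols["S1"].initial_value == 10
    parse_rule_or_init_clause("ka = lognormal(0.1, 0.25)", m)
    assert m.symbols["ka"].initial_value is None
    assert m.initial_assignments == [
        ("ka", Call("lognormal", (Num(0.1), Num(0.25))))]


def test_assignment_and_rate_rules():
    m = Model()
    rule = parse_rule_or_init_clause("x := k*y", m)
    assert rule.rule_kind == "assignment" and rule.target_id == "x"
    rule = parse_rule_or_init_clause("z' = k*z", m)
    assert rule.rule_kind == "rate" and rule.target_id == "z"


def test_zero_assignment_rule_is_rejected():
    with pytest.raises(ClauseError):
        parse_rule_or_init_clause("0 := x")


def test_substance_only_directive_order_independent():
    before, _ = parse_document("substanceOnly S1\nS1 -> ; k*S1\nS1 = 10")
    after, _ = parse_document("S1 -> ; k*S1\nS1 = 10\nsubstanceOnly S1")
    for m in (before, after):
        assert m.symbols["S1"].substance_only
        assert m.symbols["S1"].initial_value == 10
    assert semantic_equal(before, after)[0]


# ---------------------------------------------------------------------------
# inequalities: constraints and flux bounds
# ---------------------------------------------------------------------------

def test_chained_inequality_declares_parameter_constraint():
    m = Model()
    con = parse_inequality_clause("10 < J2 < 50", m)
    assert isinstance(con, Constraint)
    assert (con.lower, con.upper) == (10.0, 50.0)
    assert con.strict_lower and con.strict_upper
    assert m.symbols["J2"].kind is SymbolKind.PARAMETER


def test_inequality_on_reaction_becomes_flux_bound():
    m = Model()
    declare(m, "R1", SymbolKind.REACTION, explicit=True)
    fb = parse_inequality_clause("0 <= R1 <= 1000", m)
    assert isinstance(fb, FluxBoundSet)
    assert (fb.lower, fb.upper) == (0.0, 1000.0)


def test_single_inequality_one_sided():
    con = parse_inequality_clause("5 < X")
    assert con.lower == 5.0 and con.upper is None and con.strict_lower


def test_flux_bound_before_reaction_definition():
    """Bounds stated before the reaction line still become flux bounds."""
    m, diags = parse_document("0 <= R1 <= 1000\nR1: A -> B")
    assert not _errors(diags)
    assert not m.constraints
    assert m.flux_bounds == [FluxBoundSet("R1", 0.0, 1000.0, line=1)]


def test_strict_flux_bound_warns():
    _, diags = parse_document("R1: A -> B\n0 < R1 < 10")
    assert any(d.severity == "warning" and "strict" in d.message for d in diags)


def test_inequality_errors():
    with pytest.raises(ClauseError):
        parse_inequality_clause("1 < 2 < 3")       # middle not an identifier
    with pytest.raises(ClauseError):
        parse_inequality_clause("1 < a < b < 4")   # too many comparisons
    with pytest.raises(ClauseError):
        parse_inequality_clause("a < 2 > b")       # mixed directions


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def test_objective_forms():
    obj = parse_objective_clause("maximize R1 + R2")
    assert obj.sense == "maximize" and obj.terms == [(1.0, "R1"), (1.0, "R2")]
    obj = parse_objective_clause("minimize J")
    assert obj.sense == "minimize" and obj.terms == [(1.0, "J")]
    obj = parse_objective_clause("maximize 2 R1 - 0.5 R2")
    assert obj.terms == [(2.0, "R1"), (-0.5, "R2")]


def test_objective_rejects_nonlinear():
    with pytest.raises(ClauseError):
        parse_objective_clause("maximize R1*R2")
    with pytest.raises(ClauseError):
        parse_objective_clause("maximize R1 R2")


# ---------------------------------------------------------------------------
# dot clauses
# ---------------------------------------------------------------------------

def test_dot_uncertainty_and_layout():
    m = parse_dot_clause("x.mean = 10")
    assert m.uncertainty[0].stat == "mean" and m.uncertainty[0].value == 10
    m = parse_dot_clause("x.position = {50, 40}")
    assert m.layout.positions["x"] == (50.0, 40.0)
    m = parse_dot_clause("model.layout = on")
    assert m.layout.enabled
    m = parse_dot_clause("x.confidenceInterval = {1, 2}")
    assert m.uncertainty[0].value == (1.0, 2.0)
    m = parse_dot_clause("J0.curvePoints = {90, 70, 110, 70}")
    assert m.layout.reaction_curves["J0"] == ((90.0, 70.0), (110.0, 70.0))


def test_dot_clause_errors():
    with pytest.raises(ClauseError, match="unknown dot property"):
        parse_dot_clause("x.colour = 10")
    with pytest.raises(ClauseError, match="two numbers"):
        parse_dot_clause("x.position = {50}")
    with pytest.raises(ClauseError):
        parse_dot_clause("model.layout = maybe")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def test_annotation_and_notes():
    m = parse_annotation_clause('S1 is "http://identifiers.org/CHEBI:17234"')
    ann = m.annotations[0]
    assert (ann.element_id, ann.qualifier) == ("S1", "is")
    m = parse_annotation_clause('model notes "Markdown **context**"')
    assert m.notes[0].markdown == "Markdown **context**"


def test_unknown_qualifier_rejected():
    with pytest.raises(ClauseError, match="frobnicates"):
        parse_annotation_clause('S1 frobnicates "x"')


def test_duplicate_notes_later_wins_with_warning():
    m, diags = parse_document('model notes "first"\nmodel notes "second"')
    assert len(m.notes) == 1 and m.notes[0].markdown == "second"
    assert any(d.severity == "warning" for d in diags)


# ---------------------------------------------------------------------------
# global properties
# ---------------------------------------------------------------------------

def test_parse_is_deterministic(small_corpus):
    for text in small_corpus[:10]:
        m1, d1 = parse_document(text)
        m2, d2 = parse_document(text)
        assert semantic_equal(m1, m2)[0]
        assert [str(x) for x in d1] == [str(x) for x in d2]


def test_statement_order_robustness(small_corpus):
    rng = random.Random(3)
    for text in small_corpus[:12]:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        base, _ = parse_document("\n".join(lines))
        shuffled = lines[:]
        rng.shuffle(shuffled)
        m, diags = parse_document("\n".join(shuffled))
        assert not _errors(diags)
        equal, diffs = semantic_equal(base, m)
        assert equal, diffs


def test_fuzz_crash_freedom(small_corpus):
    """Random mutations of valid models produce diagnostics, never crashes."""
    rng = random.Random(99)
    noise = "{}()<>=;:.,\"'$->\\+-*/^ \n\tabc012−é"
    for i in range(300):
        base = small_corpus[i % len(small_corpus)]
        chars = list(base) if base else list("A -> B")
        for _ in range(rng.randint(1, 12)):
            op = rng.randint(0, 2)
            pos = rng.randrange(max(len(chars), 1))
            if op == 0 and chars:
                chars[pos % len(chars)] = rng.choice(noise)
            elif op == 1:
                chars.insert(pos, rng.choice(noise))
            elif chars:
                del chars[pos % len(chars)]
        mutated = "".join(chars)
        model, diags = parse_document(mutated)  # must not raise
        assert isinstance(diags, list)


def test_referenced_ids_always_in_symbol_table(small_corpus):
    from rxnscript import validate
    for text in small_corpus:
        m, diags = parse_document(text)
        if _errors(diags):
            continue
        assert not any("unresolved" in d.message for d in validate(m))
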