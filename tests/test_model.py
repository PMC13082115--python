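"""Symbol table, kind promotion, validation and semantic equality."""

import random

import pytest

from rxnscript import (
    FluxBoundSet, Model, Rule, SymbolConflictError, SymbolKind, declare,
    parse_document, semantic_equal, validate,
)
from rxnscript.mathexpr import parse_expression


# ---------------------------------------------------------------------------
# declare / kind promotion
# ---------------------------------------------------------------------------

def test_reaction_side_then_math_reference_stays_species():
    m = Model()
    declare(m, "S1", SymbolKind.SPECIES)        # reactant role
    entry = declare(m, "S1", SymbolKind.PARAMETER)  # later math reference
    assert entry.kind is SymbolKind.SPECIES
    assert m.symbols["S1"] is entry


def test_math_reference_defaults_to_parameter():
    m = Model()
    entry = declare(m, "k1", SymbolKind.PARAMETER)
    assert entry.kind is SymbolKind.PARAMETER and not entry.declared_explicitly


def test_implicit_parameter_promotes_to_structural_roles():
    m = Model()
    declare(m, "n", SymbolKind.PARAMETER)
    entry = declare(m, "n", SymbolKind.STOICHIOMETRY)  # coefficient position
    assert entry.kind is SymbolKind.STOICHIOMETRY


def test_explicit_redeclaration_conflict():
    m = Model()
    declare(m, "X", SymbolKind.PARAMETER, explicit=True)
    with pytest.raises(SymbolConflictError):
        declare(m, "X", SymbolKind.COMPARTMENT, explicit=True)


def test_promotion_away_from_explicit_kind_is_error():
    m = Model()
    declare(m, "C", SymbolKind.COMPARTMENT, explicit=True)
    with pytest.raises(SymbolConflictError):
        declare(m, "C", SymbolKind.SPECIES)  # e.g. appearing on a reaction side


def test_time_is_reserved():
    m = Model()
    with pytest.raises(SymbolConflictError):
        declare(m, "time", SymbolKind.PARAMETER)


_FIXTURE = [
    "J0: S1 -> S2; k1*S1",
    "J1: 2 S2 -> S3",
    "n0 = 3",
    "J2: n0 S3 -> S1; k2*S3^n0",
    "10 < p < 50",
    "substanceOnly S3",
    "S2 in C1",
]


def test_kind_promotion_is_order_independent():
    """Final kinds depend on the roles an id plays, not statement order."""
    base, diags = parse_document("\n".join(_FIXTURE))
    assert not [d for d in diags if d.severity == "error"]
    kinds = {k: v.kind for k, v in base.symbols.items()}
    rng = random.Random(1)
    for _ in range(10):
        lines = _FIXTURE[:]
        rng.shuffle(lines)
        m, d = parse_document("\n".join(lines))
        assert not [x for x in d if x.severity == "error"], lines
        assert {k: v.kind for k, v in m.symbols.items()} == kinds


# ---------------------------------------------------------------------------
# validate
# ---------------------------------------------------------------------------

def test_validate_empty_model():
    assert validate(Model(id="m")) == []


def test_validate_flux_bound_on_declared_reaction():
    m, _ = parse_document("R1: A -> B\n0 <= R1 <= 1000")
    assert validate(m) == []
    assert m.flux_bounds == [FluxBoundSet("R1", 0.0, 1000.0, line=2)]


def test_validate_rule_on_const_symbol():
    m, _ = parse_document("const k = 5")
    m.rules.append(Rule("assignment", math=parse_expression("2"), target_id="k"))
    diags = validate(m)
    assert len(diags) == 1 and diags[0].severity == "error"
    assert "const" in diags[0].message


def test_validate_unresolved_reference():
    m = Model()
    m.flux_bounds.append(FluxBoundSet("nowhere", 0, 10))
    assert any("unresolved" in d.message for d in validate(m))


def test_validate_is_idempotent_and_pure(small_corpus):
    for text in small_corpus[:10]:
        m, _ = parse_document(text)
        first = [str(d) for d in validate(m)]
        second = [str(d) for d in validate(m)]
        assert first == second == []


# ---------------------------------------------------------------------------
# semantic_equal
# ---------------------------------------------------------------------------

def test_semantic_equal_reflexive():
    m, _ = parse_document("\n".join(_FIXTURE))
    equal, diffs = semantic_equal(m, m)
    assert equal and not diffs


def test_semantic_equal_ignores_statement_order():
    a, _ = parse_document("J0: A -> B\nJ1: B -> C")
    b, _ = parse_document("J1: B -> C\nJ0: A -> B")
    assert semantic_equal(a, b)[0]


def test_semantic_equal_detects_changed_flux_bound():
    a, _ = parse_document("R1: A -> B\n0 <= R1 <= 1000")
    b, _ = parse_document("R1: A -> B\n0 <= R1 <= 999")
    equal, diffs = semantic_equal(a, b)
    assert not equal
    assert len(diffs) == 2  # the 1000-bound entry and the 999-bound entry
    assert all("flux bounds" in d for d in diffs)


def test_semantic_equal_is_equivalence_on_corpus(small_corpus):
    models = [parse_document(t)[0] for t in small_corpus[:8]]
    for i, a in enumerate(models):
        assert semantic_equal(a, a)[0]                       # reflexive
        for b in models[i + 1:]:
            assert semantic_equal(a, b)[0] == semantic_equal(b, a)[0]  # symmetric
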