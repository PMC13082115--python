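"""Fixture generation, round-trip checking and Monte-Carlo utilities.

The seeded model generator produces language text exercising any chosen
combination of features (events, rules, constraints, flux-balance data,
distribution draws, layout, annotations, named stoichiometries,
substance-only species).  Its output always parses cleanly, which makes it
the corpus for the round-trip property: text -> model -> SBML -> model ->
text must preserve everything.

``priority_race`` reproduces the two-event priority experiment: two
simultaneous events whose priorities are drawn from uniform(0,1) and
uniform(0,2) — the wider draw wins in 3/4 of runs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields as _dc_fields

import numpy as np

from .mathexpr import evaluate, fmt_number, parse_expression
from .model import Model, Diagnostic, semantic_equal
from .parser import parse_document
from .sbml import export_sbml, import_sbml
from .serializer import serialize_model

__all__ = ["GeneratorConfig", "generate_model", "RoundTripReport",
           "roundtrip_check", "priority_race"]

FEATURE_FLAGS = ("events", "rules", "constraints", "fbc", "distrib",
                 "layout", "annotations", "named_stoich", "substance_only")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_species: int = 6
    n_reactions: int = 5
    events: bool = False
    rules: bool = False
    constraints: bool = False
    fbc: bool = False
    distrib: bool = False
    layout: bool = False
    annotations: bool = False
    named_stoich: bool = False
    substance_only: bool = False
    max_math_depth: int = 3

    def __post_init__(self):
        if self.n_species < 0 or self.n_reactions < 0:
            raise ValueError("species and reaction counts must be >= 0")
        if not 0 <= self.max_math_depth <= 8:
            raise ValueError("max_math_depth must be between 0 and 8")


def _random_expr(rng: random.Random, leaves: list[str], depth: int) -> str:
    if depth <= 0 or rng.random() < 0.35:
        roll = rng.random()
        if roll < 0.5 and leaves:
            return rng.choice(leaves)
        return fmt_number(rng.choice([0.5, 1, 2, 3, 5, 10]))
    op = rng.choice(["+", "-", "*", "*", "/"])
    left = _random_expr(rng, leaves, depth - 1)
    right = _random_expr(rng, leaves, depth - 1)
    if op == "/":
        right = fmt_number(rng.choice([2, 4, 10]))  # avoid symbolic denominators
    if op in "+-":
        return f"({left} {op} {right})"
    return f"({left}{op}{right})"


def generate_model(config: GeneratorConfig) -> str:
    """Deterministically generate model text for a configuration.

    The same configuration always yields the same text, the text parses
    with zero error diagnostics, and every enabled feature appears at
    least once whenever the species/reaction budget allows it.
    """
    rng = random.Random(config.seed)
    lines: list[str] = []
    n_sp = config.n_species
    species = [f"S{i}" for i in range(n_sp)]
    n_rxn = config.n_reactions if n_sp > 0 else 0
    reactions = [f"J{i}" for i in range(n_rxn)]

    if n_sp == 0 and n_rxn == 0 and not any(
            getattr(config, flag) for flag in FEATURE_FLAGS):
        return ""

    # reactions with mass-action-style rate laws
    for i, rid in enumerate(reactions):
        n_react = rng.choice([1, 1, 2]) if n_sp > 1 else 1
        n_prod = rng.choice([1, 1, 2]) if n_sp > 1 else 1
        reactants = rng.sample(species, min(n_react, n_sp))
        products = rng.sample(species, min(n_prod, n_sp))

        def term(sid: str) -> str:
            coeff = rng.choice([None, None, None, 2, 3])
            return f"{coeff} {sid}" if coeff else sid

        lhs = " + ".join(term(s) for s in reactants)
        rhs = " + ".join(term(s) for s in products)
        if config.named_stoich and i == 0:
            lhs = f"n0 {reactants[0]}" + ("".join(
                " + " + term(s) for s in reactants[1:]))
        rate_leaves = [f"k{i}"] + reactants
        rate = f"k{i}*{reactants[0]}"
        if config.max_math_depth > 1 and rng.random() < 0.5:
            rate = f"k{i}*" + _random_expr(rng, rate_leaves[1:],
                                           config.max_math_depth - 1)
        lines.append(f"{rid}: {lhs} -> {rhs}; {rate}")
        lines.append(f"k{i} = {fmt_number(rng.choice([0.1, 0.5, 1, 2.5]))}")

    if config.named_stoich and reactions:
        lines.append("n0 = 3")

    if config.substance_only and species:
        chosen = species[: 1 + (n_sp > 3)]
        lines.append("substanceOnly " + ", ".join(chosen))

    for sid in species:
        if rng.random() < 0.5:
            lines.append(f"{sid} = {fmt_number(rng.choice([0, 1, 5, 10]))}")

    if config.rules:
        leaves = species if species else ["g0"]
        lines.append(f"w0 := {_random_expr(rng, leaves, max(config.max_math_depth - 1, 1))}")
        lines.append(f"w1' = {_random_expr(rng, leaves + ['w0'], 1)}")
        lines.append("w1 = 0")
        if len(species) >= 2:
            lines.append(f"A0: 0 = {species[0]} + {species[1]} - wtot")
            lines.append(f"wtot = {fmt_number(rng.choice([1, 2, 10]))}")

    if config.events:
        prio = ", priority = uniform(0, 2)" if config.distrib else ""
        guard = f" and {species[0]} < 1" if species else ""
        lines.append(f"E0: at time > 3{guard}: kp0 = 10")
        lines.append(f"E1: at time > 2{prio}: kp1 = 5, kp0 = 0")

    if config.constraints:
        lines.append("10 < c0 < 50")
        lines.append("c1 <= 5")
        lines.append(f"c0 = {fmt_number(rng.choice([20, 30, 42]))}")

    if config.fbc and reactions:
        bounded = reactions[: min(2, len(reactions))]
        lines.append(f"0 <= {bounded[0]} <= 1000")
        if len(bounded) > 1:
            lines.append(f"{bounded[1]} >= 0")
        obj_terms = " + ".join(
            ([bounded[0]] + [f"2 {r}" for r in bounded[1:2]]))
        lines.append(f"maximize {obj_terms}")

    if config.distrib:
        lines.append("ka = lognormal(0.1, 0.25)")
        if species:
            lines.append(f"{species[0]}.mean = 10")
            lines.append(f"{species[0]}.standardDeviation = 2")
        lines.append("ka.confidenceInterval = {0.5, 1.5}")

    if config.annotations:
        if species:
            lines.append(f'{species[0]} is "http://identifiers.org/chebi/CHEBI:17234"')
            lines.append(f'{species[0]} isVersionOf "http://identifiers.org/go/GO:0005575"')
        lines.append('model is "http://identifiers.org/biomodels.db/MODEL0000000001"')
        lines.append('model notes "Generated fixture model."')

    if config.layout:
        lines.append("model.layout = on")
        for i, sid in enumerate(species):
            x = 50 + (i % 4) * 150
            y = 50 + (i // 4) * 150
            lines.append(f"{sid}.position = {{{x}, {y}}}")
            lines.append(f"{sid}.size = {{80, 40}}")
        if reactions:
            lines.append(f"{reactions[0]}.centroid = {{110, 70}}")
            lines.append(f"{reactions[0]}.curvePoints = {{90, 70, 110, 70, 130, 70}}")
        if rng.random() < 0.5:
            lines.append('model.styleTemplate = "Escher"')

    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Round-trip checking
# ---------------------------------------------------------------------------

@dataclass
class RoundTripReport:
    passed: bool
    diagnostics: list[Diagnostic] = field(default_factory=list)
    text_differences: list[str] = field(default_factory=list)
    sbml_differences: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)
    canonical_text: str = ""
    second_text: str = ""

    def summary(self) -> str:
        if self.passed:
            return "round trip: PASS"
        parts = ["round trip: FAIL"]
        parts += [f"  diagnostic {d}" for d in self.diagnostics]
        parts += [f"  text diff: {d}" for d in self.text_differences]
        parts += [f"  sbml diff: {d}" for d in self.sbml_differences]
        parts += [f"  dropped: {c} ({r})" for c, r in self.dropped]
        return "\n".join(parts)


def roundtrip_check(text: str) -> RoundTripReport:
    """Run text -> model -> SBML -> model -> text and compare both hops.

    Passes iff the reparsed canonical text matches the original model, the
    SBML importer reproduces the model with nothing dropped, and the
    second-generation canonical text is byte-identical to the first.
    """
    model, diags = parse_document(text)
    errors = [d for d in diags if d.severity == "error"]
    if errors:
        return RoundTripReport(passed=False, diagnostics=errors)
    t1 = serialize_model(model)
    reparsed, rediags = parse_document(t1)
    report = RoundTripReport(passed=True, canonical_text=t1)
    report.diagnostics = [d for d in rediags if d.severity == "error"]
    equal, diffs = semantic_equal(model, reparsed)
    if not equal:
        report.text_differences = diffs
    export = export_sbml(model)
    imported = import_sbml(export.document)
    report.dropped = list(imported.dropped)
    equal, diffs = semantic_equal(model, imported.model)
    if not equal:
        report.sbml_differences = diffs
    report.second_text = serialize_model(imported.model)
    report.passed = (not report.diagnostics and not report.text_differences
                     and not report.sbml_differences and not report.dropped
                     and report.second_text == t1)
    return report


# ---------------------------------------------------------------------------
# Priority race
# ---------------------------------------------------------------------------

def priority_race(n: int, seed: int) -> float:
    """Fraction of trials in which uniform(0,2) beats uniform(0,1).

    Each trial evaluates the two priority expressions with a shared seeded
    generator, mirroring two simultaneous events racing on sampled
    priorities.  Analytically the wider draw wins with probability 3/4.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prio_narrow = parse_expression("uniform(0, 1)")
    prio_wide = parse_expression("uniform(0, 2)")
    wins = 0
    for _ in range(n):
        u0 = evaluate(prio_narrow, {}, rng)
        u1 = evaluate(prio_wide, {}, rng)
        if u1 > u0:
            wins += 1
    return wins / n
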