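"""Deterministic rendering of a Model back to language text.

The output is a canonical form: fixed section order (header, compartments,
species, reactions, rules, initializations, events, constraints, flux
bounds, objectives, uncertainty, annotations, notes, layout), single-space
canonical whitespace, ASCII ``->`` arrows, LF line endings, and statements
sorted by identifier within each section.  Sorting makes the text a pure
function of the model's semantic content, so any two models that compare
semantic-equal serialize byte-identically and serialize∘parse is a
fixpoint after a single round.
"""

from __future__ import annotations

import math as _math

from .mathexpr import MathNode, fmt_number, render_expression
from .model import (
    Model, Reaction, SpeciesReference, SymbolKind, validate,
)

__all__ = ["serialize_model", "SerializationError"]

_INDENT = "  "


class SerializationError(ValueError):
    """The model has validation errors and cannot be rendered."""

    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        listing = "; ".join(str(d) for d in diagnostics[:5])
        super().__init__(f"model does not validate: {listing}")


def _escape(text: str) -> str:
    return (text.replace("\\", "\\\\").replace('"', '\\"')
            .replace("\n", "\\n"))


def _num_or_expr(v) -> str:
    if isinstance(v, MathNode):
        return render_expression(v)
    return fmt_number(v)


def _ref_text(ref: SpeciesReference, boundary: bool) -> str:
    name = ("$" if boundary else "") + ref.species_id
    if ref.stoichiometry_id is not None:
        return f"{ref.stoichiometry_id} {name}"
    if ref.stoichiometry is not None and ref.stoichiometry != 1:
        return f"{fmt_number(ref.stoichiometry)} {name}"
    return name


def serialize_model(model: Model) -> str:
    """Render a validated model to canonical text (UTF-8, LF endings)."""
    errors = [d for d in validate(model) if d.severity == "error"]
    if errors:
        raise SerializationError(errors)

    syms = model.symbols
    lines: list[str] = [f"model {model.id}"]

    def emit(stmt: str) -> None:
        lines.append(_INDENT + stmt)

    def is_boundary(sid: str) -> bool:
        entry = syms.get(sid)
        return bool(entry and entry.is_boundary)

    # --- compartments -----------------------------------------------------
    for entry in sorted(syms.values(), key=lambda e: e.id):
        if entry.kind is SymbolKind.COMPARTMENT:
            emit(("const " if entry.is_const else "") + f"compartment {entry.id}")

    # --- species ----------------------------------------------------------
    # explicit declarations are needed where reactions alone cannot
    # re-establish the species' attributes (compartment, boundary, const,
    # or a species that appears in no reaction at all)
    reaction_species = {ref.species_id
                        for r in model.reactions
                        for ref in r.reactants + r.products}
    for entry in sorted(syms.values(), key=lambda e: e.id):
        if entry.kind is not SymbolKind.SPECIES:
            continue
        needs_decl = (entry.compartment is not None or entry.is_const
                      or entry.id not in reaction_species
                      or (entry.is_boundary and entry.id not in reaction_species))
        if needs_decl:
            stmt = ("const " if entry.is_const else "") + "species "
            stmt += ("$" if entry.is_boundary else "") + entry.id
            if entry.compartment is not None:
                stmt += f" in {entry.compartment}"
            emit(stmt)
    substance_only = sorted(e.id for e in syms.values()
                            if e.kind is SymbolKind.SPECIES and e.substance_only)
    if substance_only:
        emit("substanceOnly " + ", ".join(substance_only))

    # --- stray declarations -----------------------------------------------
    # stoichiometry ids not used in any reaction, const parameters without
    # an initialization, and parameters referenced by nothing that declares
    # them would vanish on reparse without an explicit line
    used_stoich = {ref.stoichiometry_id
                   for r in model.reactions
                   for ref in r.reactants + r.products
                   if ref.stoichiometry_id is not None}
    for entry in sorted(syms.values(), key=lambda e: e.id):
        if entry.kind is SymbolKind.STOICHIOMETRY and entry.id not in used_stoich:
            emit(f"stoichiometry {entry.id}")
        elif entry.kind is SymbolKind.PARAMETER:
            if entry.is_const and entry.initial_value is None:
                emit(f"const parameter {entry.id}")
            elif not entry.is_const and entry.initial_value is None \
                    and not _is_reachable(model, entry.id):
                emit(f"parameter {entry.id}")

    # --- reactions --------------------------------------------------------
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        emit(_reaction_text(rxn, is_boundary))

    # --- rules ------------------------------------------------------------
    def rule_key(rule):
        return (rule.rule_kind, rule.id or "", rule.target_id or "")

    for rule in sorted(model.rules, key=rule_key):
        if rule.rule_kind == "algebraic":
            emit(f"{rule.id}: 0 = {render_expression(rule.math)}")
        elif rule.rule_kind == "assignment":
            emit(f"{rule.target_id} := {render_expression(rule.math)}")
        else:
            emit(f"{rule.target_id}' = {render_expression(rule.math)}")

    # --- initializations --------------------------------------------------
    for entry in sorted(syms.values(), key=lambda e: e.id):
        if entry.initial_value is not None:
            prefix = "const " if (entry.is_const
                                  and entry.kind is SymbolKind.PARAMETER) else ""
            emit(f"{prefix}{entry.id} = {fmt_number(entry.initial_value)}")
    for target, expr in sorted(model.initial_assignments, key=lambda p: p[0]):
        emit(f"{target} = {render_expression(expr)}")

    # --- events -----------------------------------------------------------
    for ev in sorted(model.events, key=lambda e: e.id):
        head = f"{ev.id}: at {render_expression(ev.trigger)}"
        if ev.priority is not None:
            head += f", priority = {render_expression(ev.priority)}"
        body = ", ".join(f"{t} = {render_expression(x)}" for t, x in ev.assignments)
        emit(f"{head}: {body}")

    # --- constraints ------------------------------------------------------
    for con in sorted(model.constraints, key=lambda c: c.symbol_id):
        lo_op = "<" if con.strict_lower else "<="
        hi_op = "<" if con.strict_upper else "<="
        if con.lower is not None and con.upper is not None:
            emit(f"{_num_or_expr(con.lower)} {lo_op} {con.symbol_id} "
                 f"{hi_op} {_num_or_expr(con.upper)}")
        elif con.lower is not None:
            emit(f"{_num_or_expr(con.lower)} {lo_op} {con.symbol_id}")
        else:
            emit(f"{con.symbol_id} {hi_op} {_num_or_expr(con.upper)}")

    # --- flux bounds ------------------------------------------------------
    for fb in sorted(model.flux_bounds, key=lambda f: f.reaction_id):
        has_lower = fb.lower != -_math.inf
        has_upper = fb.upper != _math.inf
        if has_lower and has_upper:
            emit(f"{fmt_number(fb.lower)} <= {fb.reaction_id} <= {fmt_number(fb.upper)}")
        elif has_lower:
            emit(f"{fb.reaction_id} >= {fmt_number(fb.lower)}")
        elif has_upper:
            emit(f"{fb.reaction_id} <= {fmt_number(fb.upper)}")

    # --- objectives (declaration order: the first one is active) ----------
    for obj in model.objectives:
        parts: list[str] = []
        for i, (coeff, rid) in enumerate(obj.terms):
            mag = abs(coeff)
            term = rid if mag == 1 else f"{fmt_number(mag)} {rid}"
            if i == 0:
                parts.append(("-" if coeff < 0 else "") + term)
            else:
                parts.append(("- " if coeff < 0 else "+ ") + term)
        emit(f"{obj.sense} " + " ".join(parts))

    # --- uncertainty ------------------------------------------------------
    for unc in sorted(model.uncertainty, key=lambda u: (u.element_id, u.stat)):
        if unc.stat == "confidenceInterval":
            lo, hi = unc.value
            emit(f"{unc.element_id}.confidenceInterval = "
                 f"{{{fmt_number(lo)}, {fmt_number(hi)}}}")
        else:
            emit(f"{unc.element_id}.{unc.stat} = {fmt_number(unc.value)}")

    # --- annotations ------------------------------------------------------
    for ann in sorted(model.annotations,
                      key=lambda a: (a.element_id, a.qualifier, a.uri)):
        emit(f'{ann.element_id} {ann.qualifier} "{_escape(ann.uri)}"')

    # --- notes ------------------------------------------------------------
    for note in sorted(model.notes, key=lambda n: n.element_id):
        emit(f'{note.element_id} notes "{_escape(note.markdown)}"')

    # --- layout -----------------------------------------------------------
    lay = model.layout
    if lay.enabled:
        emit("model.layout = on")
    for sid, (x, y) in sorted(lay.positions.items()):
        prop = ("centroid" if model.kind_of(sid) is SymbolKind.REACTION
                else "position")
        emit(f"{sid}.{prop} = {{{fmt_number(x)}, {fmt_number(y)}}}")
    for sid, (w, h) in sorted(lay.sizes.items()):
        emit(f"{sid}.size = {{{fmt_number(w)}, {fmt_number(h)}}}")
    for rid, points in sorted(lay.reaction_curves.items()):
        flat = ", ".join(f"{fmt_number(x)}, {fmt_number(y)}" for x, y in points)
        emit(f"{rid}.curvePoints = {{{flat}}}")
    if lay.style_template is not None:
        emit(f'model.styleTemplate = "{_escape(lay.style_template)}"')

    lines.append("end")
    return "\n".join(lines) + "\n"


def _reaction_text(rxn: Reaction, is_boundary) -> str:
    lhs = " + ".join(_ref_text(r, is_boundary(r.species_id)) for r in rxn.reactants)
    rhs = " + ".join(_ref_text(r, is_boundary(r.species_id)) for r in rxn.products)
    text = f"{rxn.id}: " + (lhs + " " if lhs else "") + "->" + (" " + rhs if rhs else "")
    if rxn.kinetic_math is not None:
        text += f"; {render_expression(rxn.kinetic_math)}"
    return text


def _is_reachable(model: Model, sid: str) -> bool:
    """True if reparse of the canonical text would re-create this symbol."""
    from .mathexpr import free_symbols

    def in_math(node) -> bool:
        return node is not None and sid in free_symbols(node)

    for rxn in model.reactions:
        if in_math(rxn.kinetic_math):
            return True
    for rule in model.rules:
        if rule.target_id == sid or in_math(rule.math):
            return True
    for ev in model.events:
        if in_math(ev.trigger) or in_math(ev.priority):
            return True
        for t, x in ev.assignments:
            if t == sid or in_math(x):
                return True
    for con in model.constraints:
        if con.symbol_id == sid or in_math(con.lower if isinstance(con.lower, MathNode) else None) \
                or in_math(con.upper if isinstance(con.upper, MathNode) else None):
            return True
    for obj in model.objectives:
        if any(rid == sid for _, rid in obj.terms):
            return True
    for t, x in model.initial_assignments:
        if t == sid or in_math(x):
            return True
    for unc in model.uncertainty:
        if unc.element_id == sid:
            return True
    for ann in model.annotations:
        if ann.element_id == sid:
            return True
    for note in model.notes:
        if note.element_id == sid:
            return True
    lay = model.layout
    if sid in lay.positions or sid in lay.sizes or sid in lay.reaction_curves:
        return True
    return False
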