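"""Internal model representation.

A :class:`Model` is the hub of the pipeline: the text parser and the SBML
importer both populate it, and the text serializer and SBML exporter both
read it.  It keeps a single flat symbol table in which every identifier has
exactly one kind (species, parameter, compartment, reaction, ...).  Kinds
are mostly *inferred*: an id first seen inside math defaults to parameter,
appearing on a reaction side promotes it to species, appearing in
coefficient position promotes it to a named stoichiometry, and an
``in <id>`` context promotes it to a compartment.  Explicit declarations
pin a kind; contradictory explicit kinds are conflicts.
"""

from __future__ import annotations

import enum
import math as _math
from dataclasses import dataclass, field
from typing import Optional, Union

from .mathexpr import MathNode, fmt_number, free_symbols, render_expression, walk, Call, Sym

__all__ = [
    "SymbolKind", "SymbolEntry", "SpeciesReference", "Reaction", "Event",
    "Rule", "Constraint", "FluxBoundSet", "Objective", "AnnotationEntry",
    "NotesEntry", "UncertaintyStat", "LayoutInfo", "Model", "Diagnostic",
    "SymbolConflictError", "declare", "validate", "semantic_equal",
]

MODEL_TOKEN = "model"

# MIRIAM qualifier keywords accepted by the annotation statement.
QUALIFIERS = frozenset({
    "is", "isVersionOf", "hasPart", "isPartOf", "isDescribedBy",
    "hasProperty", "isPropertyOf", "hasTaxon", "isDerivedFrom",
    "isInstanceOf", "hasInstance", "origin", "created", "creator",
})

UNCERTAINTY_STATS = ("mean", "standardDeviation", "variance", "confidenceInterval")


class SymbolKind(str, enum.Enum):
    SPECIES = "species"
    PARAMETER = "parameter"
    COMPARTMENT = "compartment"
    REACTION = "reaction"
    EVENT = "event"
    RULE = "rule"
    STOICHIOMETRY = "stoichiometry"
    MODEL = "model"


class SymbolConflictError(ValueError):
    """Two declarations assign incompatible kinds to one identifier."""


@dataclass
class Diagnostic:
    severity: str  # "error" | "warning"
    line: int
    message: str

    def __str__(self) -> str:
        return f"{self.severity}:{self.line}:{self.message}"


@dataclass
class SymbolEntry:
    id: str
    kind: SymbolKind
    declared_explicitly: bool = False
    is_const: bool = False
    is_boundary: bool = False
    substance_only: bool = False
    compartment: Optional[str] = None
    initial_value: Optional[float] = None


@dataclass
class SpeciesReference:
    species_id: str
    stoichiometry: Optional[float] = None
    stoichiometry_id: Optional[str] = None

    def __post_init__(self):
        if self.stoichiometry is None and self.stoichiometry_id is None:
            self.stoichiometry = 1.0


@dataclass
class Reaction:
    id: str
    reactants: list[SpeciesReference] = field(default_factory=list)
    products: list[SpeciesReference] = field(default_factory=list)
    kinetic_math: Optional[MathNode] = None
    reversible: bool = True
    line: int = 1


@dataclass
class Event:
    id: str
    trigger: MathNode = None
    priority: Optional[MathNode] = None
    assignments: list[tuple[str, MathNode]] = field(default_factory=list)
    persistent: bool = True
    initial_value_trigger: bool = True
    use_values_from_trigger_time: bool = True
    line: int = 1


@dataclass
class Rule:
    rule_kind: str  # "assignment" | "rate" | "algebraic"
    math: MathNode = None
    id: Optional[str] = None          # algebraic rules only
    target_id: Optional[str] = None   # assignment / rate rules only
    line: int = 1


NumericOrMath = Union[float, MathNode]


@dataclass
class Constraint:
    symbol_id: str
    lower: Optional[NumericOrMath] = None
    upper: Optional[NumericOrMath] = None
    strict_lower: bool = False
    strict_upper: bool = False
    line: int = 1


@dataclass
class FluxBoundSet:
    reaction_id: str
    lower: float = -_math.inf
    upper: float = _math.inf
    line: int = 1


@dataclass
class Objective:
    sense: str  # "maximize" | "minimize"
    terms: list[tuple[float, str]] = field(default_factory=list)
    line: int = 1


@dataclass
class AnnotationEntry:
    element_id: str  # identifier or the token "model"
    qualifier: str
    uri: str
    line: int = 1


@dataclass
class NotesEntry:
    element_id: str
    markdown: str
    line: int = 1


@dataclass
class UncertaintyStat:
    element_id: str
    stat: str  # mean | standardDeviation | variance | confidenceInterval
    value: Union[float, tuple[float, float]] = 0.0
    line: int = 1


@dataclass
class LayoutInfo:
    enabled: bool = False
    positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    sizes: dict[str, tuple[float, float]] = field(default_factory=dict)
    reaction_curves: dict[str, tuple[tuple[float, float], ...]] = field(default_factory=dict)
    style_template: Optional[str] = None

    def is_empty(self) -> bool:
        return not (self.enabled or self.positions or self.sizes
                    or self.reaction_curves or self.style_template)


@dataclass
class Model:
    id: str = "__main"
    symbols: dict[str, SymbolEntry] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    flux_bounds: list[FluxBoundSet] = field(default_factory=list)
    objectives: list[Objective] = field(default_factory=list)
    annotations: list[AnnotationEntry] = field(default_factory=list)
    notes: list[NotesEntry] = field(default_factory=list)
    uncertainty: list[UncertaintyStat] = field(default_factory=list)
    initial_assignments: list[tuple[str, MathNode]] = field(default_factory=list)
    layout: LayoutInfo = field(default_factory=LayoutInfo)

    def kind_of(self, sid: str) -> Optional[SymbolKind]:
        entry = self.symbols.get(sid)
        return entry.kind if entry else None


# ---------------------------------------------------------------------------
# Declaration / kind promotion
# ---------------------------------------------------------------------------

# kinds an implicitly-declared parameter may be promoted to
_PROMOTABLE = {SymbolKind.SPECIES, SymbolKind.COMPARTMENT, SymbolKind.REACTION,
               SymbolKind.EVENT, SymbolKind.RULE, SymbolKind.STOICHIOMETRY,
               SymbolKind.MODEL}


def declare(model: Model, sid: str, kind: SymbolKind, explicit: bool = False) -> SymbolEntry:
    """Register (or re-register) an identifier with a kind.

    The promotion ladder: an id first seen in math defaults to parameter;
    structural roles (reaction side, coefficient position, ``in`` context,
    statement labels) promote it.  A plain math reference (implicit
    parameter) never demotes an established kind.  Conflicting explicit
    kinds, or promotion away from an explicit kind, raise
    :class:`SymbolConflictError`.
    """
    if kind is not SymbolKind.MODEL and sid == "time":
        raise SymbolConflictError("'time' is reserved for simulation time")
    entry = model.symbols.get(sid)
    if entry is None:
        entry = SymbolEntry(id=sid, kind=kind, declared_explicitly=explicit)
        model.symbols[sid] = entry
        return entry
    if entry.kind is kind:
        entry.declared_explicitly = entry.declared_explicitly or explicit
        return entry
    # kinds differ
    if not explicit and kind is SymbolKind.PARAMETER:
        # a math reference is compatible with every established kind
        return entry
    if entry.kind is SymbolKind.PARAMETER and not entry.declared_explicitly \
            and kind in _PROMOTABLE:
        entry.kind = kind
        entry.declared_explicitly = entry.declared_explicitly or explicit
        return entry
    raise SymbolConflictError(
        f"'{sid}' is already declared as {entry.kind.value}"
        f"{' (explicitly)' if entry.declared_explicitly else ''}"
        f" and cannot be redeclared as {kind.value}")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _err(diags: list[Diagnostic], line: int, msg: str) -> None:
    diags.append(Diagnostic("error", max(line, 1), msg))


def validate(model: Model) -> list[Diagnostic]:
    """Check every referential and structural invariant of the model.

    Pure and idempotent; an empty return value means the model is
    exportable to both text and SBML.
    """
    diags: list[Diagnostic] = []
    syms = model.symbols

    def resolve(sid: str, want: SymbolKind | None, line: int, ctx: str) -> None:
        entry = syms.get(sid)
        if entry is None:
            _err(diags, line, f"{ctx}: unresolved identifier '{sid}'")
        elif want is not None and entry.kind is not want:
            _err(diags, line,
                 f"{ctx}: '{sid}' is a {entry.kind.value}, expected {want.value}")

    for entry in syms.values():
        if entry.substance_only and entry.kind is not SymbolKind.SPECIES:
            _err(diags, 1, f"substanceOnly applies only to species, not '{entry.id}'")
        if entry.is_boundary and entry.kind is not SymbolKind.SPECIES:
            _err(diags, 1, f"boundary flag applies only to species, not '{entry.id}'")
        if entry.compartment is not None:
            resolve(entry.compartment, SymbolKind.COMPARTMENT, 1,
                    f"compartment of '{entry.id}'")

    def check_math(node: MathNode | None, line: int, ctx: str) -> None:
        if node is None:
            return
        for sid in free_symbols(node):
            resolve(sid, None, line, ctx)
        for sub in walk(node):
            if isinstance(sub, Call) and sub.name == "rateOf":
                arg = sub.args[0]
                if isinstance(arg, Sym):
                    entry = syms.get(arg.id)
                    if entry and entry.kind in (SymbolKind.REACTION, SymbolKind.EVENT,
                                                SymbolKind.RULE, SymbolKind.MODEL):
                        _err(diags, line,
                             f"{ctx}: rateOf argument '{arg.id}' is not a value symbol")

    for rxn in model.reactions:
        if not rxn.reactants and not rxn.products:
            _err(diags, rxn.line, f"reaction '{rxn.id}' has no reactants or products")
        resolve(rxn.id, SymbolKind.REACTION, rxn.line, "reaction id")
        for ref in rxn.reactants + rxn.products:
            resolve(ref.species_id, SymbolKind.SPECIES, rxn.line,
                    f"reaction '{rxn.id}'")
            if ref.stoichiometry is not None and ref.stoichiometry_id is not None:
                _err(diags, rxn.line,
                     f"reaction '{rxn.id}': both numeric and named stoichiometry set")
            if ref.stoichiometry is not None and not ref.stoichiometry > 0:
                _err(diags, rxn.line,
                     f"reaction '{rxn.id}': stoichiometry must be positive")
            if ref.stoichiometry_id is not None:
                resolve(ref.stoichiometry_id, SymbolKind.STOICHIOMETRY, rxn.line,
                        f"reaction '{rxn.id}'")
        check_math(rxn.kinetic_math, rxn.line, f"rate law of '{rxn.id}'")

    rule_targets: set[str] = set()
    for rule in model.rules:
        if rule.rule_kind == "algebraic":
            if rule.target_id is not None:
                _err(diags, rule.line, "algebraic rule cannot have a target")
        else:
            if rule.target_id is None:
                _err(diags, rule.line, f"{rule.rule_kind} rule needs a target")
            else:
                resolve(rule.target_id, None, rule.line, f"{rule.rule_kind} rule")
                entry = syms.get(rule.target_id)
                if entry and entry.is_const:
                    _err(diags, rule.line,
                         f"{rule.rule_kind} rule targets const symbol '{rule.target_id}'")
                if rule.target_id in rule_targets:
                    _err(diags, rule.line,
                         f"'{rule.target_id}' is the target of more than one rule")
                rule_targets.add(rule.target_id)
        check_math(rule.math, rule.line, "rule math")

    for ev in model.events:
        resolve(ev.id, SymbolKind.EVENT, ev.line, "event id")
        if ev.trigger is None:
            _err(diags, ev.line, f"event '{ev.id}' has no trigger")
        else:
            check_math(ev.trigger, ev.line, f"trigger of '{ev.id}'")
        check_math(ev.priority, ev.line, f"priority of '{ev.id}'")
        if not ev.assignments:
            _err(diags, ev.line, f"event '{ev.id}' has no assignments")
        for target, expr in ev.assignments:
            resolve(target, None, ev.line, f"event '{ev.id}' assignment")
            entry = syms.get(target)
            if entry and entry.is_const:
                _err(diags, ev.line,
                     f"event '{ev.id}' assigns to const symbol '{target}'")
            check_math(expr, ev.line, f"assignment in '{ev.id}'")

    for con in model.constraints:
        resolve(con.symbol_id, None, con.line, "constraint")
        if con.lower is None and con.upper is None:
            _err(diags, con.line, f"constraint on '{con.symbol_id}' has no bounds")
        if isinstance(con.lower, (int, float)) and isinstance(con.upper, (int, float)) \
                and con.lower > con.upper:
            _err(diags, con.line,
                 f"constraint on '{con.symbol_id}': lower bound exceeds upper bound")
        for bound in (con.lower, con.upper):
            if isinstance(bound, MathNode):
                check_math(bound, con.line, "constraint bound")

    for fb in model.flux_bounds:
        resolve(fb.reaction_id, SymbolKind.REACTION, fb.line, "flux bound")
        if fb.lower > fb.upper:
            _err(diags, fb.line,
                 f"flux bounds on '{fb.reaction_id}': lower bound exceeds upper bound")

    for obj in model.objectives:
        if not obj.terms:
            _err(diags, obj.line, "objective has no terms")
        for _, rid in obj.terms:
            resolve(rid, SymbolKind.REACTION, obj.line, "objective")

    for ann in model.annotations:
        if ann.qualifier not in QUALIFIERS:
            _err(diags, ann.line, f"unknown annotation qualifier '{ann.qualifier}'")
        if ann.element_id != MODEL_TOKEN:
            resolve(ann.element_id, None, ann.line, "annotation")

    seen_notes: set[str] = set()
    for note in model.notes:
        if note.element_id != MODEL_TOKEN:
            resolve(note.element_id, None, note.line, "notes")
        if note.element_id in seen_notes:
            _err(diags, note.line,
                 f"more than one notes entry for '{note.element_id}'")
        seen_notes.add(note.element_id)

    for unc in model.uncertainty:
        resolve(unc.element_id, None, unc.line, "uncertainty")
        if unc.stat not in UNCERTAINTY_STATS:
            _err(diags, unc.line, f"unknown uncertainty statistic '{unc.stat}'")
        elif unc.stat == "confidenceInterval":
            if not (isinstance(unc.value, tuple) and len(unc.value) == 2):
                _err(diags, unc.line, "confidenceInterval needs a {lo, hi} pair")
            elif unc.value[0] > unc.value[1]:
                _err(diags, unc.line, "confidenceInterval: lo exceeds hi")
        elif not isinstance(unc.value, (int, float)):
            _err(diags, unc.line, f"{unc.stat} needs a single numeric value")

    for target, expr in model.initial_assignments:
        resolve(target, None, 1, "initial assignment")
        check_math(expr, 1, f"initial assignment of '{target}'")

    lay = model.layout
    for mapping, what in ((lay.positions, "position"), (lay.sizes, "size")):
        for sid, pair in mapping.items():
            resolve(sid, None, 1, f"layout {what}")
            if not all(_math.isfinite(v) for v in pair):
                _err(diags, 1, f"layout {what} of '{sid}' is not finite")
    for rid, points in lay.reaction_curves.items():
        resolve(rid, SymbolKind.REACTION, 1, "layout curve")
        if len(points) < 2:
            _err(diags, 1, f"curve of '{rid}' needs at least two points")
        for pt in points:
            if not all(_math.isfinite(v) for v in pt):
                _err(diags, 1, f"curve point of '{rid}' is not finite")

    return diags


# ---------------------------------------------------------------------------
# Semantic equality
# ---------------------------------------------------------------------------

def _num_or_math(v) -> str:
    if v is None:
        return ""
    if isinstance(v, MathNode):
        return render_expression(v)
    return fmt_number(v)


def _ref_sig(ref: SpeciesReference) -> tuple:
    return (ref.species_id, _num_or_math(ref.stoichiometry), ref.stoichiometry_id or "")


def _signatures(m: Model) -> dict[str, object]:
    sig: dict[str, object] = {}
    sig["model id"] = m.id
    sig["symbols"] = {
        e.id: (e.kind.value, e.is_const, e.is_boundary, e.substance_only,
               e.compartment or "", _num_or_math(e.initial_value))
        for e in m.symbols.values()
    }
    sig["reactions"] = sorted(
        (r.id, tuple(_ref_sig(x) for x in r.reactants),
         tuple(_ref_sig(x) for x in r.products),
         _num_or_math(r.kinetic_math), r.reversible)
        for r in m.reactions)
    sig["events"] = sorted(
        (e.id, _num_or_math(e.trigger), _num_or_math(e.priority),
         tuple((t, _num_or_math(x)) for t, x in e.assignments),
         e.persistent, e.initial_value_trigger, e.use_values_from_trigger_time)
        for e in m.events)
    sig["rules"] = sorted(
        (r.rule_kind, r.id or "", r.target_id or "", _num_or_math(r.math))
        for r in m.rules)
    sig["constraints"] = sorted(
        (c.symbol_id, _num_or_math(c.lower), _num_or_math(c.upper),
         c.strict_lower, c.strict_upper)
        for c in m.constraints)
    sig["flux bounds"] = sorted(
        (f.reaction_id, fmt_number(f.lower), fmt_number(f.upper))
        for f in m.flux_bounds)
    # objective order is semantic: the first declared objective is active
    sig["objectives"] = [
        (o.sense, tuple((fmt_number(c), r) for c, r in o.terms))
        for o in m.objectives]
    sig["annotations"] = sorted((a.element_id, a.qualifier, a.uri) for a in m.annotations)
    sig["notes"] = sorted((n.element_id, n.markdown) for n in m.notes)
    sig["uncertainty"] = sorted(
        (u.element_id, u.stat,
         tuple(fmt_number(v) for v in u.value) if isinstance(u.value, tuple)
         else fmt_number(u.value))
        for u in m.uncertainty)
    sig["initial assignments"] = sorted(
        (t, _num_or_math(x)) for t, x in m.initial_assignments)
    lay = m.layout
    sig["layout"] = (
        lay.enabled,
        tuple(sorted((k, v) for k, v in lay.positions.items())),
        tuple(sorted((k, v) for k, v in lay.sizes.items())),
        tuple(sorted((k, v) for k, v in lay.reaction_curves.items())),
        lay.style_template or "")
    return sig


def semantic_equal(a: Model, b: Model, max_differences: int = 20
                   ) -> tuple[bool, list[str]]:
    """Compare two models up to statement order.

    Returns ``(equal, differences)`` where differences lists at most
    ``max_differences`` human-readable discrepancies.  Math is compared by
    canonical rendering, collections as order-insensitive multisets —
    except objectives, whose order decides which one is active.
    """
    sa, sb = _signatures(a), _signatures(b)
    diffs: list[str] = []
    for key in sa:
        va, vb = sa[key], sb[key]
        if va == vb:
            continue
        if isinstance(va, dict):
            for k in sorted(set(va) | set(vb)):
                if va.get(k) != vb.get(k):
                    diffs.append(f"{key}[{k}]: {va.get(k)!r} != {vb.get(k)!r}")
        elif isinstance(va, list):
            local: list[str] = []
            for item in va:
                if item not in vb:
                    local.append(f"{key}: only in first: {item!r}")
            for item in vb:
                if item not in va:
                    local.append(f"{key}: only in second: {item!r}")
            if not local:
                local.append(f"{key}: order differs: {va!r} != {vb!r}")
            diffs.extend(local)
        else:
            diffs.append(f"{key}: {va!r} != {vb!r}")
    diffs = diffs[:max_differences]
    return (not diffs, diffs)
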