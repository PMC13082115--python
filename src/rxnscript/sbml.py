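"""SBML Level 3 Version 2 export and import.

The exporter maps a validated :class:`~rxnscript.model.Model` onto an SBML
document using the Core namespace plus — only when the model actually uses
them — the Flux Balance Constraints (fbc, version 2), Distributions
(distrib, version 1) and Layout (version 1) packages.  The importer is its
inverse on the supported construct set; SBML constructs outside that set
(unit definitions, function definitions, event delays, piecewise math,
unknown packages, ...) are recorded in ``ImportReport.dropped`` rather than
silently lost.

Mapping contract highlights
---------------------------
* ``substanceOnly`` species carry ``hasOnlySubstanceUnits="true"`` and
  their initial value populates ``initialAmount`` (else
  ``initialConcentration``).
* Species without a compartment are placed in an auto-created
  ``default_compartment`` of size 1 (SBML requires one); the importer
  elides that compartment again when nothing else references it.
* Named stoichiometries become identified ``speciesReference`` elements;
  their numeric value travels as an initial assignment.
* Chained-inequality constraints become ``constraint`` elements whose math
  is the conjunction of the two comparisons (``lt`` vs ``leq`` preserves
  strictness).
* Flux bounds become constant parameters ``<rid>_lb`` / ``<rid>_ub``
  referenced from the reaction's fbc bound attributes.
* CV-term annotations become RDF bags under the biology- (elements) or
  model- (model) qualifier namespace; notes wrap the Markdown verbatim in
  an XHTML ``<pre>`` block.
"""

from __future__ import annotations

import math as _math
import re
from dataclasses import dataclass, field

from lxml import etree

from . import mathexpr
from .mathexpr import (
    Call, MathMLError, MathNode, Num, Sym, fmt_number, math_element, walk,
)
from .model import (
    AnnotationEntry, Constraint, Diagnostic, Event, FluxBoundSet, Model,
    NotesEntry, Objective, Reaction, Rule, SpeciesReference, SymbolKind,
    UncertaintyStat, declare, validate,
)

__all__ = [
    "ExportReport", "ImportReport", "export_sbml", "import_sbml",
    "check_document", "SBMLExportError", "SBMLImportError",
]

CORE_NS = "http://www.sbml.org/sbml/level3/version2/core"
CORE_NS_V1 = "http://www.sbml.org/sbml/level3/version1/core"
FBC_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
DISTRIB_NS = "http://www.sbml.org/sbml/level3/version1/distrib/version1"
LAYOUT_NS = "http://www.sbml.org/sbml/level3/version1/layout/version1"
MATHML_NS = mathexpr.MATHML_NS
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"
XHTML_NS = "http://www.w3.org/1999/xhtml"
STYLE_NS = "urn:rxnscript:style-template"

_KNOWN_PACKAGE_NS = {FBC_NS, DISTRIB_NS, LAYOUT_NS}
_KNOWN_NS = _KNOWN_PACKAGE_NS | {CORE_NS, CORE_NS_V1, MATHML_NS, RDF_NS,
                                 BQBIOL_NS, BQMODEL_NS, XHTML_NS, STYLE_NS}

DEFAULT_COMPARTMENT = "default_compartment"

# fallback grid for `model.layout = on` without coordinates
_GRID_BOX = (80.0, 40.0)
_GRID_PITCH = 150.0
_GRID_COLUMNS = 4


class SBMLExportError(ValueError):
    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        listing = "; ".join(str(d) for d in diagnostics[:5])
        super().__init__(f"model does not validate: {listing}")


class SBMLImportError(ValueError):
    pass


@dataclass
class ExportReport:
    document: str
    packages_used: set[str] = field(default_factory=set)
    warnings: list[Diagnostic] = field(default_factory=list)


@dataclass
class ImportReport:
    model: Model
    dropped: list[tuple[str, str]] = field(default_factory=list)


def _sbml_number(v: float) -> str:
    if v == _math.inf:
        return "INF"
    if v == -_math.inf:
        return "-INF"
    return fmt_number(v)


def _parse_sbml_number(text: str) -> float:
    t = text.strip()
    if t == "INF":
        return _math.inf
    if t == "-INF":
        return -_math.inf
    if t == "NaN":
        return _math.nan
    return float(t)


def _uses_draws(model: Model) -> bool:
    for node in _all_math(model):
        for sub in walk(node):
            if isinstance(sub, Call) and sub.name in mathexpr.DRAW_FUNCTIONS:
                return True
    return False


def _all_math(model: Model):
    for r in model.reactions:
        if r.kinetic_math is not None:
            yield r.kinetic_math
    for rule in model.rules:
        if rule.math is not None:
            yield rule.math
    for ev in model.events:
        if ev.trigger is not None:
            yield ev.trigger
        if ev.priority is not None:
            yield ev.priority
        for _, x in ev.assignments:
            yield x
    for _, x in model.initial_assignments:
        yield x
    for con in model.constraints:
        for bound in (con.lower, con.upper):
            if isinstance(bound, MathNode):
                yield bound


# ===========================================================================
# Export
# ===========================================================================

def export_sbml(model: Model) -> ExportReport:
    """Serialize a validated model to an SBML L3V2 document.

    Package namespaces are declared only when the corresponding features
    are present, so feature-free models export with Core alone.  Identical
    models produce byte-identical documents.
    """
    errors = [d for d in validate(model) if d.severity == "error"]
    if errors:
        raise SBMLExportError(errors)
    warnings: list[Diagnostic] = []

    use_fbc = bool(model.flux_bounds or model.objectives)
    use_distrib = bool(model.uncertainty) or _uses_draws(model)
    use_layout = not model.layout.is_empty()
    packages = set()

    nsmap = {None: CORE_NS}
    if use_fbc:
        nsmap["fbc"] = FBC_NS
        packages.add("fbc")
    if use_distrib:
        nsmap["distrib"] = DISTRIB_NS
        packages.add("distrib")
    if use_layout:
        nsmap["layout"] = LAYOUT_NS
        packages.add("layout")

    root = etree.Element(f"{{{CORE_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    if use_fbc:
        root.set(f"{{{FBC_NS}}}required", "false")
    if use_distrib:
        root.set(f"{{{DISTRIB_NS}}}required", "true")
    if use_layout:
        root.set(f"{{{LAYOUT_NS}}}required", "false")

    mel = etree.SubElement(root, f"{{{CORE_NS}}}model")
    mel.set("id", model.id)
    if use_fbc:
        mel.set(f"{{{FBC_NS}}}strict", "false")

    notes_by_element = {n.element_id: n for n in model.notes}
    anns_by_element: dict[str, list[AnnotationEntry]] = {}
    for ann in model.annotations:
        anns_by_element.setdefault(ann.element_id, []).append(ann)
    uncs_by_element: dict[str, list[UncertaintyStat]] = {}
    for unc in model.uncertainty:
        uncs_by_element.setdefault(unc.element_id, []).append(unc)

    def decorate(el: etree._Element, eid: str) -> None:
        """Attach notes / RDF annotation / distrib uncertainty to an SBase."""
        note = notes_by_element.get(eid)
        anns = anns_by_element.get(eid, [])
        uncs = uncs_by_element.get(eid, [])
        if note is not None:
            notes_el = etree.Element(f"{{{CORE_NS}}}notes")
            body = etree.SubElement(notes_el, f"{{{XHTML_NS}}}body",
                                    nsmap={None: XHTML_NS})
            pre = etree.SubElement(body, f"{{{XHTML_NS}}}pre")
            pre.text = note.markdown
            el.insert(0, notes_el)
        if anns:
            metaid = f"meta_{model.id if eid == 'model' else eid}"
            el.set("metaid", metaid)
            ann_el = etree.SubElement(el, f"{{{CORE_NS}}}annotation")
            qual_ns = BQMODEL_NS if eid == "model" else BQBIOL_NS
            prefix = "bqmodel" if eid == "model" else "bqbiol"
            rdf = etree.SubElement(
                ann_el, f"{{{RDF_NS}}}RDF",
                nsmap={"rdf": RDF_NS, prefix: qual_ns})
            desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
            desc.set(f"{{{RDF_NS}}}about", "#" + metaid)
            by_qual: dict[str, list[str]] = {}
            for a in anns:
                by_qual.setdefault(a.qualifier, []).append(a.uri)
            for qual in sorted(by_qual):
                qel = etree.SubElement(desc, f"{{{qual_ns}}}{qual}")
                bag = etree.SubElement(qel, f"{{{RDF_NS}}}Bag")
                for uri in sorted(by_qual[qual]):
                    li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
                    li.set(f"{{{RDF_NS}}}resource", uri)
        if uncs:
            lst = etree.SubElement(el, f"{{{DISTRIB_NS}}}listOfUncertainties")
            unc_el = etree.SubElement(lst, f"{{{DISTRIB_NS}}}uncertainty")
            params = etree.SubElement(
                unc_el, f"{{{DISTRIB_NS}}}listOfUncertParameters")
            for u in sorted(uncs, key=lambda u: u.stat):
                if u.stat == "confidenceInterval":
                    span = etree.SubElement(
                        params, f"{{{DISTRIB_NS}}}uncertSpan")
                    span.set(f"{{{DISTRIB_NS}}}type", "confidenceInterval")
                    span.set(f"{{{DISTRIB_NS}}}valueLower", fmt_number(u.value[0]))
                    span.set(f"{{{DISTRIB_NS}}}valueUpper", fmt_number(u.value[1]))
                else:
                    par = etree.SubElement(
                        params, f"{{{DISTRIB_NS}}}uncertParameter")
                    par.set(f"{{{DISTRIB_NS}}}type", u.stat)
                    par.set(f"{{{DISTRIB_NS}}}value", fmt_number(u.value))

    decorate(mel, "model")

    syms = model.symbols
    species = sorted((e for e in syms.values() if e.kind is SymbolKind.SPECIES),
                     key=lambda e: e.id)
    compartments = sorted((e for e in syms.values()
                           if e.kind is SymbolKind.COMPARTMENT),
                          key=lambda e: e.id)
    parameters = sorted((e for e in syms.values()
                         if e.kind is SymbolKind.PARAMETER),
                        key=lambda e: e.id)
    stoichs = sorted((e for e in syms.values()
                      if e.kind is SymbolKind.STOICHIOMETRY),
                     key=lambda e: e.id)

    need_default_compartment = any(e.compartment is None for e in species)

    # --- compartments -----------------------------------------------------
    if compartments or need_default_compartment:
        lst = etree.SubElement(mel, f"{{{CORE_NS}}}listOfCompartments")
        entries = list(compartments)
        if need_default_compartment and DEFAULT_COMPARTMENT not in syms:
            entries.append(None)  # placeholder for the default compartment
        for entry in sorted(entries, key=lambda e: e.id if e else DEFAULT_COMPARTMENT):
            cel = etree.SubElement(lst, f"{{{CORE_NS}}}compartment")
            if entry is None:
                cel.set("id", DEFAULT_COMPARTMENT)
                cel.set("size", "1")
                cel.set("constant", "true")
            else:
                cel.set("id", entry.id)
                if entry.initial_value is not None:
                    cel.set("size", _sbml_number(entry.initial_value))
                cel.set("constant", "true" if entry.is_const else "false")
                decorate(cel, entry.id)

    # --- species ----------------------------------------------------------
    if species:
        lst = etree.SubElement(mel, f"{{{CORE_NS}}}listOfSpecies")
        for entry in species:
            sel = etree.SubElement(lst, f"{{{CORE_NS}}}species")
            sel.set("id", entry.id)
            sel.set("compartment", entry.compartment or DEFAULT_COMPARTMENT)
            if entry.initial_value is not None:
                slot = ("initialAmount" if entry.substance_only
                        else "initialConcentration")
                sel.set(slot, _sbml_number(entry.initial_value))
            sel.set("hasOnlySubstanceUnits",
                    "true" if entry.substance_only else "false")
            sel.set("boundaryCondition", "true" if entry.is_boundary else "false")
            sel.set("constant", "true" if entry.is_const else "false")
            decorate(sel, entry.id)

    # --- parameters (incl. flux-bound parameters) -------------------------
    bound_params: list[tuple[str, float]] = []
    bound_attr: dict[tuple[str, str], str] = {}
    taken = set(syms)
    for fb in sorted(model.flux_bounds, key=lambda f: f.reaction_id):
        for side, value in (("lb", fb.lower), ("ub", fb.upper)):
            pid = f"{fb.reaction_id}_{side}"
            n = 0
            while pid in taken:
                n += 1
                pid = f"{fb.reaction_id}_{side}{n}"
            taken.add(pid)
            bound_params.append((pid, value))
            bound_attr[(fb.reaction_id, side)] = pid
    if parameters or bound_params:
        lst = etree.SubElement(mel, f"{{{CORE_NS}}}listOfParameters")
        for entry in parameters:
            pel = etree.SubElement(lst, f"{{{CORE_NS}}}parameter")
            pel.set("id", entry.id)
            if entry.initial_value is not None:
                pel.set("value", _sbml_number(entry.initial_value))
            pel.set("constant", "true" if entry.is_const else "false")
            decorate(pel, entry.id)
        for pid, value in bound_params:
            pel = etree.SubElement(lst, f"{{{CORE_NS}}}parameter")
            pel.set("id", pid)
            pel.set("value", _sbml_number(value))
            pel.set("constant", "true")

    # --- initial assignments ----------------------------------------------
    ia_items: list[tuple[str, MathNode]] = sorted(
        model.initial_assignments, key=lambda p: p[0])
    for entry in stoichs:
        if entry.initial_value is not None:
            ia_items.append((entry.id, Num(entry.initial_value)))
    ia_items.sort(key=lambda p: p[0])
    if ia_items:
        lst = etree.SubElement(mel, f"{{{CORE_NS}}}listOfInitialAssignments")
        for target, expr in ia_items:
            iel = etree.SubElement(lst, f"{{{CORE_NS}}}initialAssignment")
            iel.set("symbol", target)
            iel.append(math_element(expr))

    # --- rules ------------------------------------------------------------
    if model.rules:
        lst = etree.SubElement(mel, f"{{{CORE_NS}}}listOfRules")
        for rule in sorted(model.rules,
                           key=lambda r: (r.rule_kind, r.id or "", r.target_id or "")):
            if rule.rule_kind == "algebraic":
                rel = etree.SubElement(lst, f"{{{CORE_NS}}}algebraicRule")
                if rule.id:
                    rel.set("id", rule.id)
            elif rule.rule_kind == "assignment":
                rel = etree.SubElement(lst, f"{{{CORE_NS}}}assignmentRule")
                rel.set("variable", rule.target_id)
            else:
                rel = etree.SubElement(lst, f"{{{CORE_NS}}}rateRule")
                rel.set("variable", rule.target_id)
            rel.append(math_element(rule.math))

    # --- constraints ------------------------------------------------------
    if model.constraints:
        lst = etree.SubElement(mel, f"{{{CORE_NS}}}listOfConstraints")
        for con in sorted(model.constraints, key=lambda c: c.symbol_id):
            cel = etree.SubElement(lst, f"{{{CORE_NS}}}constraint")
            cel.append(math_element(_constraint_math(con)))

    # --- reactions --------------------------------------------------------
    if model.reactions:
        lst = etree.SubElement(mel, f"{{{CORE_NS}}}listOfReactions")
        for rxn in sorted(model.reactions, key=lambda r: r.id):
            rel = etree.SubElement(lst, f"{{{CORE_NS}}}reaction")
            rel.set("id", rxn.id)
            rel.set("reversible", "true" if rxn.reversible else "false")
            if (rxn.id, "lb") in bound_attr:
                rel.set(f"{{{FBC_NS}}}lowerFluxBound", bound_attr[(rxn.id, "lb")])
                rel.set(f"{{{FBC_NS}}}upperFluxBound", bound_attr[(rxn.id, "ub")])
            decorate(rel, rxn.id)
            for tag, refs in (("listOfReactants", rxn.reactants),
                              ("listOfProducts", rxn.products)):
                if not refs:
                    continue
                refs_el = etree.SubElement(rel, f"{{{CORE_NS}}}{tag}")
                for ref in refs:
                    sref = etree.SubElement(refs_el,
                                            f"{{{CORE_NS}}}speciesReference")
                    sref.set("species", ref.species_id)
                    if ref.stoichiometry_id is not None:
                        sref.set("id", ref.stoichiometry_id)
                        sref.set("constant", "false")
                    else:
                        sref.set("stoichiometry", fmt_number(ref.stoichiometry))
                        sref.set("constant", "true")
            if rxn.kinetic_math is not None:
                klaw = etree.SubElement(rel, f"{{{CORE_NS}}}kineticLaw")
                klaw.append(math_element(rxn.kinetic_math))

    # --- events -----------------------------------------------------------
    if model.events:
        lst = etree.SubElement(mel, f"{{{CORE_NS}}}listOfEvents")
        for ev in sorted(model.events, key=lambda e: e.id):
            eel = etree.SubElement(lst, f"{{{CORE_NS}}}event")
            eel.set("id", ev.id)
            eel.set("useValuesFromTriggerTime",
                    "true" if ev.use_values_from_trigger_time else "false")
            trig = etree.SubElement(eel, f"{{{CORE_NS}}}trigger")
            trig.set("persistent", "true" if ev.persistent else "false")
            trig.set("initialValue",
                     "true" if ev.initial_value_trigger else "false")
            trig.append(math_element(ev.trigger))
            if ev.priority is not None:
                pri = etree.SubElement(eel, f"{{{CORE_NS}}}priority")
                pri.append(math_element(ev.priority))
            asn_lst = etree.SubElement(eel, f"{{{CORE_NS}}}listOfEventAssignments")
            for target, expr in ev.assignments:
                ael = etree.SubElement(asn_lst, f"{{{CORE_NS}}}eventAssignment")
                ael.set("variable", target)
                ael.append(math_element(expr))

    # --- fbc objectives ---------------------------------------------------
    if model.objectives:
        lst = etree.SubElement(mel, f"{{{FBC_NS}}}listOfObjectives")
        lst.set(f"{{{FBC_NS}}}activeObjective", "obj0")
        for i, obj in enumerate(model.objectives):
            oel = etree.SubElement(lst, f"{{{FBC_NS}}}objective")
            oel.set(f"{{{FBC_NS}}}id", f"obj{i}")
            oel.set(f"{{{FBC_NS}}}type", obj.sense)
            flx_lst = etree.SubElement(oel, f"{{{FBC_NS}}}listOfFluxObjectives")
            for coeff, rid in obj.terms:
                fel = etree.SubElement(flx_lst, f"{{{FBC_NS}}}fluxObjective")
                fel.set(f"{{{FBC_NS}}}reaction", rid)
                fel.set(f"{{{FBC_NS}}}coefficient", fmt_number(coeff))

    # --- layout -----------------------------------------------------------
    if use_layout:
        _export_layout(mel, model, warnings)

    for entry in stoichs:
        used = any(ref.stoichiometry_id == entry.id
                   for r in model.reactions
                   for ref in r.reactants + r.products)
        if not used:
            warnings.append(Diagnostic(
                "warning", 1,
                f"stoichiometry '{entry.id}' is used by no reaction and was "
                "not exported"))

    document = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                              pretty_print=True).decode()
    return ExportReport(document=document, packages_used=packages,
                        warnings=warnings)


def _constraint_math(con: Constraint) -> MathNode:
    from .mathexpr import BoolOp, Cmp

    def as_node(v) -> MathNode:
        if isinstance(v, MathNode):
            return v
        if v < 0:
            return mathexpr.Neg(Num(-v))
        return Num(v)

    sym = Sym(con.symbol_id)
    parts: list[MathNode] = []
    if con.lower is not None:
        parts.append(Cmp("<" if con.strict_lower else "<=",
                         as_node(con.lower), sym))
    if con.upper is not None:
        parts.append(Cmp("<" if con.strict_upper else "<=",
                         sym, as_node(con.upper)))
    if len(parts) == 2:
        return BoolOp("and", tuple(parts))
    return parts[0]


def _layout_glyph_positions(model: Model) -> tuple[dict, dict]:
    """Explicit coordinates, or the fallback grid when none are given."""
    lay = model.layout
    if lay.positions or lay.sizes or lay.reaction_curves:
        return dict(lay.positions), dict(lay.sizes)
    # deterministic grid: species boxes on a fixed pitch, row-major in
    # id order (stands in for an auto-layout engine, which is out of scope)
    positions: dict[str, tuple[float, float]] = {}
    sizes: dict[str, tuple[float, float]] = {}
    ids = sorted(e.id for e in model.symbols.values()
                 if e.kind is SymbolKind.SPECIES)
    for i, sid in enumerate(ids):
        row, col = divmod(i, _GRID_COLUMNS)
        positions[sid] = (50.0 + col * _GRID_PITCH, 50.0 + row * _GRID_PITCH)
        sizes[sid] = _GRID_BOX
    return positions, sizes


def _export_layout(mel: etree._Element, model: Model, warnings) -> None:
    lay = model.layout
    positions, sizes = _layout_glyph_positions(model)
    lst = etree.SubElement(mel, f"{{{LAYOUT_NS}}}listOfLayouts")
    lel = etree.SubElement(lst, f"{{{LAYOUT_NS}}}layout")
    lel.set(f"{{{LAYOUT_NS}}}id", "layout0")
    if lay.style_template is not None:
        ann = etree.SubElement(lel, f"{{{CORE_NS}}}annotation")
        st = etree.SubElement(ann, f"{{{STYLE_NS}}}styleTemplate",
                              nsmap={None: STYLE_NS})
        st.text = lay.style_template
    width = max([x + w for (x, _), (w, _) in
                 ((positions.get(k, (0, 0)), sizes.get(k, (0, 0)))
                  for k in set(positions) | set(sizes))] + [100.0])
    height = max([y + h for (_, y), (_, h) in
                  ((positions.get(k, (0, 0)), sizes.get(k, (0, 0)))
                   for k in set(positions) | set(sizes))] + [100.0])
    for pts in lay.reaction_curves.values():
        for x, y in pts:
            width = max(width, x)
            height = max(height, y)
    dim = etree.SubElement(lel, f"{{{LAYOUT_NS}}}dimensions")
    dim.set(f"{{{LAYOUT_NS}}}width", fmt_number(width))
    dim.set(f"{{{LAYOUT_NS}}}height", fmt_number(height))

    ids = sorted(set(positions) | set(sizes) | set(lay.reaction_curves))
    glyph_lists: dict[str, etree._Element] = {}

    def glyph_list(tag: str) -> etree._Element:
        if tag not in glyph_lists:
            glyph_lists[tag] = etree.SubElement(lel, f"{{{LAYOUT_NS}}}{tag}")
        return glyph_lists[tag]

    # group by glyph class so lists appear in a fixed order
    order = {"listOfCompartmentGlyphs": [], "listOfSpeciesGlyphs": [],
             "listOfReactionGlyphs": [], "listOfAdditionalGraphicalObjects": []}
    for sid in ids:
        kind = model.kind_of(sid)
        if kind is SymbolKind.SPECIES:
            order["listOfSpeciesGlyphs"].append(sid)
        elif kind is SymbolKind.COMPARTMENT:
            order["listOfCompartmentGlyphs"].append(sid)
        elif kind is SymbolKind.REACTION:
            order["listOfReactionGlyphs"].append(sid)
        else:
            order["listOfAdditionalGraphicalObjects"].append(sid)

    for tag, sids in order.items():
        if not sids:
            continue
        lst_el = glyph_list(tag)
        for sid in sids:
            if tag == "listOfSpeciesGlyphs":
                gel = etree.SubElement(lst_el, f"{{{LAYOUT_NS}}}speciesGlyph")
                gel.set(f"{{{LAYOUT_NS}}}species", sid)
            elif tag == "listOfCompartmentGlyphs":
                gel = etree.SubElement(lst_el, f"{{{LAYOUT_NS}}}compartmentGlyph")
                gel.set(f"{{{LAYOUT_NS}}}compartment", sid)
            elif tag == "listOfReactionGlyphs":
                gel = etree.SubElement(lst_el, f"{{{LAYOUT_NS}}}reactionGlyph")
                gel.set(f"{{{LAYOUT_NS}}}reaction", sid)
            else:
                gel = etree.SubElement(lst_el, f"{{{LAYOUT_NS}}}generalGlyph")
                gel.set(f"{{{LAYOUT_NS}}}reference", sid)
            gel.set(f"{{{LAYOUT_NS}}}id", f"glyph_{sid}")
            x, y = positions.get(sid, (0.0, 0.0))
            w, h = sizes.get(sid, (0.0, 0.0))
            if sid in positions or sid in sizes:
                bb = etree.SubElement(gel, f"{{{LAYOUT_NS}}}boundingBox")
                pos = etree.SubElement(bb, f"{{{LAYOUT_NS}}}position")
                pos.set(f"{{{LAYOUT_NS}}}x", fmt_number(x))
                pos.set(f"{{{LAYOUT_NS}}}y", fmt_number(y))
                dms = etree.SubElement(bb, f"{{{LAYOUT_NS}}}dimensions")
                dms.set(f"{{{LAYOUT_NS}}}width", fmt_number(w))
                dms.set(f"{{{LAYOUT_NS}}}height", fmt_number(h))
            points = lay.reaction_curves.get(sid)
            if points:
                curve = etree.SubElement(gel, f"{{{LAYOUT_NS}}}curve")
                segs = etree.SubElement(curve,
                                        f"{{{LAYOUT_NS}}}listOfCurveSegments")
                xsi = "http://www.w3.org/2001/XMLSchema-instance"
                for (x1, y1), (x2, y2) in zip(points, points[1:]):
                    seg = etree.SubElement(segs,
                                           f"{{{LAYOUT_NS}}}curveSegment")
                    seg.set(f"{{{xsi}}}type", "LineSegment")
                    start = etree.SubElement(seg, f"{{{LAYOUT_NS}}}start")
                    start.set(f"{{{LAYOUT_NS}}}x", fmt_number(x1))
                    start.set(f"{{{LAYOUT_NS}}}y", fmt_number(y1))
                    end = etree.SubElement(seg, f"{{{LAYOUT_NS}}}end")
                    end.set(f"{{{LAYOUT_NS}}}x", fmt_number(x2))
                    end.set(f"{{{LAYOUT_NS}}}y", fmt_number(y2))


# ===========================================================================
# Import
# ===========================================================================

def _local(el: etree._Element) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _ns(el: etree._Element) -> str:
    return etree.QName(el).namespace or "" if isinstance(el.tag, str) else ""


def _child(el: etree._Element, ns: str, name: str):
    return el.find(f"{{{ns}}}{name}")


def _children(el, ns: str, name: str):
    if el is None:
        return []
    return el.findall(f"{{{ns}}}{name}")


def _find_math(el: etree._Element):
    if el is None:
        return None
    return _child(el, MATHML_NS, "math")


class _Importer:
    def __init__(self) -> None:
        self.model = Model()
        self.dropped: list[tuple[str, str]] = []
        self.core = CORE_NS
        self._auto_event = 0
        self._auto_rule = 0

    def drop(self, construct: str, reason: str) -> None:
        self.dropped.append((construct, reason))

    def math(self, container, context: str):
        """Read the <math> child; unsupported content becomes a drop."""
        math_el = _find_math(container)
        if math_el is None:
            return None
        try:
            return mathexpr.from_mathml(math_el)
        except MathMLError as exc:
            self.drop(context, str(exc))
            return None

    def run(self, xml: str | bytes) -> ImportReport:
        data = xml.encode() if isinstance(xml, str) else xml
        try:
            root = etree.fromstring(data)
        except etree.XMLSyntaxError as exc:
            raise SBMLImportError(f"not well-formed XML: {exc}") from exc
        if _local(root) != "sbml":
            raise SBMLImportError("not an SBML document (no <sbml> root)")
        level = root.get("level", "")
        if level != "3":
            raise SBMLImportError(
                f"unsupported SBML level {level or '?'}; only Level 3 is supported")
        self.core = _ns(root)
        if self.core not in (CORE_NS, CORE_NS_V1):
            raise SBMLImportError(f"unknown SBML namespace {self.core!r}")
        for prefix, uri in (root.nsmap or {}).items():
            if uri not in _KNOWN_NS:
                self.drop(f"package {uri}", "unsupported package namespace")

        mel = _child(root, self.core, "model")
        if mel is None:
            raise SBMLImportError("document has no <model> element")
        self.model.id = mel.get("id", "__main")

        for name in ("listOfUnitDefinitions", "listOfFunctionDefinitions"):
            if _child(mel, self.core, name) is not None:
                self.drop(name, "not representable in the language")

        self.import_compartments(mel)
        self.import_species(mel)
        bound_param_ids = self.collect_bound_params(mel)
        self.import_parameters(mel, bound_param_ids)
        self.import_reactions(mel, bound_param_ids)
        self.import_initial_assignments(mel)
        self.import_rules(mel)
        self.import_constraints(mel)
        self.import_events(mel)
        self.import_objectives(mel)
        self.import_layout(mel)
        self.import_decorations(mel, "model")
        self.elide_default_compartment()
        self.reconcile_constraints()
        return ImportReport(model=self.model, dropped=self.dropped)

    # -- pieces ------------------------------------------------------------

    def import_decorations(self, el: etree._Element, eid: str) -> None:
        notes_el = _child(el, self.core, "notes")
        if notes_el is not None:
            pre = notes_el.find(f".//{{{XHTML_NS}}}pre")
            text = (pre.text or "") if pre is not None \
                else "".join(notes_el.itertext()).strip()
            self.model.notes.append(NotesEntry(element_id=eid, markdown=text))
        ann_el = _child(el, self.core, "annotation")
        if ann_el is not None:
            self.import_annotation(ann_el, eid)
        lst = _child(el, DISTRIB_NS, "listOfUncertainties")
        if lst is not None:
            for unc_el in _children(lst, DISTRIB_NS, "uncertainty"):
                params = _child(unc_el, DISTRIB_NS, "listOfUncertParameters")
                container = params if params is not None else unc_el
                for par in container:
                    if not isinstance(par.tag, str):
                        continue
                    ptype = par.get(f"{{{DISTRIB_NS}}}type", "")
                    if _local(par) == "uncertSpan" and ptype == "confidenceInterval":
                        lo = _parse_sbml_number(
                            par.get(f"{{{DISTRIB_NS}}}valueLower", "nan"))
                        hi = _parse_sbml_number(
                            par.get(f"{{{DISTRIB_NS}}}valueUpper", "nan"))
                        self.model.uncertainty.append(UncertaintyStat(
                            element_id=eid, stat="confidenceInterval",
                            value=(lo, hi)))
                    elif _local(par) == "uncertParameter" and ptype in (
                            "mean", "standardDeviation", "variance"):
                        self.model.uncertainty.append(UncertaintyStat(
                            element_id=eid, stat=ptype,
                            value=_parse_sbml_number(
                                par.get(f"{{{DISTRIB_NS}}}value", "nan"))))
                    else:
                        self.drop("uncertParameter",
                                  f"unsupported uncertainty entry on '{eid}'")

    def import_annotation(self, ann_el: etree._Element, eid: str) -> None:
        found_rdf = False
        for child in ann_el:
            if not isinstance(child.tag, str):
                continue
            if _ns(child) == RDF_NS and _local(child) == "RDF":
                found_rdf = True
                for desc in _children(child, RDF_NS, "Description"):
                    for qel in desc:
                        if not isinstance(qel.tag, str):
                            continue
                        qns, qname = _ns(qel), _local(qel)
                        if qns not in (BQBIOL_NS, BQMODEL_NS):
                            self.drop("annotation",
                                      f"unknown qualifier namespace {qns!r}")
                            continue
                        bag = _child(qel, RDF_NS, "Bag")
                        lis = _children(bag, RDF_NS, "li") if bag is not None \
                            else _children(qel, RDF_NS, "li")
                        for li in lis:
                            uri = li.get(f"{{{RDF_NS}}}resource", "")
                            self.model.annotations.append(AnnotationEntry(
                                element_id=eid, qualifier=qname, uri=uri))
            elif _ns(child) == STYLE_NS:
                continue  # handled by import_layout
            else:
                self.drop("annotation",
                          f"non-RDF annotation content on '{eid}'")
        del found_rdf

    def import_compartments(self, mel) -> None:
        lst = _child(mel, self.core, "listOfCompartments")
        for cel in _children(lst, self.core, "compartment"):
            cid = cel.get("id")
            if not cid:
                continue
            entry = declare(self.model, cid, SymbolKind.COMPARTMENT, explicit=True)
            entry.is_const = cel.get("constant", "true") == "true"
            if cel.get("size") is not None:
                entry.initial_value = _parse_sbml_number(cel.get("size"))
            self.import_decorations(cel, cid)

    def import_species(self, mel) -> None:
        lst = _child(mel, self.core, "listOfSpecies")
        for sel in _children(lst, self.core, "species"):
            sid = sel.get("id")
            if not sid:
                continue
            entry = declare(self.model, sid, SymbolKind.SPECIES, explicit=True)
            entry.compartment = sel.get("compartment")
            entry.substance_only = sel.get("hasOnlySubstanceUnits") == "true"
            entry.is_boundary = sel.get("boundaryCondition") == "true"
            entry.is_const = sel.get("constant") == "true"
            amount, conc = sel.get("initialAmount"), sel.get("initialConcentration")
            if entry.substance_only:
                if amount is not None:
                    entry.initial_value = _parse_sbml_number(amount)
                elif conc is not None:
                    self.drop("species", f"initialConcentration on substance-only "
                                         f"species '{sid}'")
            else:
                if conc is not None:
                    entry.initial_value = _parse_sbml_number(conc)
                elif amount is not None:
                    self.drop("species", f"initialAmount on concentration "
                                         f"species '{sid}'")
            self.import_decorations(sel, sid)

    def collect_bound_params(self, mel) -> set[str]:
        ids: set[str] = set()
        lst = _child(mel, self.core, "listOfReactions")
        for rel in _children(lst, self.core, "reaction"):
            for attr in ("lowerFluxBound", "upperFluxBound"):
                pid = rel.get(f"{{{FBC_NS}}}{attr}")
                if pid:
                    ids.add(pid)
        return ids

    def import_parameters(self, mel, bound_param_ids: set[str]) -> None:
        lst = _child(mel, self.core, "listOfParameters")
        for pel in _children(lst, self.core, "parameter"):
            pid = pel.get("id")
            if not pid:
                continue
            if pid in bound_param_ids:
                continue  # re-materialized as a FluxBoundSet
            entry = declare(self.model, pid, SymbolKind.PARAMETER, explicit=True)
            entry.is_const = pel.get("constant") == "true"
            if pel.get("value") is not None:
                entry.initial_value = _parse_sbml_number(pel.get("value"))
            self.import_decorations(pel, pid)

    def import_reactions(self, mel, bound_param_ids: set[str]) -> None:
        lst = _child(mel, self.core, "listOfReactions")
        bound_values: dict[str, float] = {}
        plist = _child(mel, self.core, "listOfParameters")
        for pel in _children(plist, self.core, "parameter"):
            if pel.get("id") in bound_param_ids and pel.get("value") is not None:
                bound_values[pel.get("id")] = _parse_sbml_number(pel.get("value"))
        for rel in _children(lst, self.core, "reaction"):
            rid = rel.get("id")
            if not rid:
                continue
            declare(self.model, rid, SymbolKind.REACTION, explicit=True)
            rxn = Reaction(id=rid,
                           reversible=rel.get("reversible", "true") == "true")
            for tag, target in (("listOfReactants", rxn.reactants),
                                ("listOfProducts", rxn.products)):
                refs_el = _child(rel, self.core, tag)
                for sref in _children(refs_el, self.core, "speciesReference"):
                    species_id = sref.get("species", "")
                    declare(self.model, species_id, SymbolKind.SPECIES)
                    sref_id = sref.get("id")
                    if sref_id:
                        declare(self.model, sref_id, SymbolKind.STOICHIOMETRY)
                        target.append(SpeciesReference(
                            species_id, stoichiometry_id=sref_id))
                    else:
                        stoich = sref.get("stoichiometry")
                        target.append(SpeciesReference(
                            species_id,
                            stoichiometry=(1.0 if stoich is None
                                           else _parse_sbml_number(stoich))))
                mods = _child(rel, self.core, "listOfModifiers")
                if mods is not None and tag == "listOfReactants":
                    self.drop("modifierSpeciesReference",
                              f"modifiers of '{rid}' are not represented")
            klaw = _child(rel, self.core, "kineticLaw")
            if klaw is not None:
                if _child(klaw, self.core, "listOfLocalParameters") is not None:
                    self.drop("localParameter",
                              f"local parameters of '{rid}' are not represented")
                rxn.kinetic_math = self.math(klaw, f"kinetic law of '{rid}'")
                if rxn.kinetic_math is not None:
                    self.declare_math(rxn.kinetic_math)
            lo = rel.get(f"{{{FBC_NS}}}lowerFluxBound")
            hi = rel.get(f"{{{FBC_NS}}}upperFluxBound")
            if lo or hi:
                fb = FluxBoundSet(
                    reaction_id=rid,
                    lower=bound_values.get(lo, -_math.inf),
                    upper=bound_values.get(hi, _math.inf))
                if fb.lower != -_math.inf or fb.upper != _math.inf:
                    self.model.flux_bounds.append(fb)
            self.model.reactions.append(rxn)
            self.import_decorations(rel, rid)

    def declare_math(self, node: MathNode) -> None:
        for sid in sorted(mathexpr.free_symbols(node)):
            declare(self.model, sid, SymbolKind.PARAMETER)

    def import_initial_assignments(self, mel) -> None:
        lst = _child(mel, self.core, "listOfInitialAssignments")
        for iel in _children(lst, self.core, "initialAssignment"):
            target = iel.get("symbol", "")
            expr = self.math(iel, f"initial assignment of '{target}'")
            if expr is None:
                continue
            entry = declare(self.model, target, SymbolKind.PARAMETER)
            if isinstance(expr, Num):
                entry.initial_value = expr.value
            elif isinstance(expr, mathexpr.Neg) and isinstance(expr.child, Num):
                entry.initial_value = -expr.child.value
            else:
                self.declare_math(expr)
                self.model.initial_assignments.append((target, expr))

    def import_rules(self, mel) -> None:
        lst = _child(mel, self.core, "listOfRules")
        if lst is None:
            return
        for rel in lst:
            if not isinstance(rel.tag, str):
                continue
            name = _local(rel)
            if name == "algebraicRule":
                math = self.math(rel, "algebraic rule")
                if math is None:
                    continue
                rid = rel.get("id")
                if not rid:
                    rid = f"_A{self._auto_rule}"
                    while rid in self.model.symbols:
                        self._auto_rule += 1
                        rid = f"_A{self._auto_rule}"
                    self._auto_rule += 1
                declare(self.model, rid, SymbolKind.RULE, explicit=True)
                self.declare_math(math)
                self.model.rules.append(Rule("algebraic", math=math, id=rid))
            elif name in ("assignmentRule", "rateRule"):
                target = rel.get("variable", "")
                math = self.math(rel, f"rule for '{target}'")
                if math is None:
                    continue
                declare(self.model, target, SymbolKind.PARAMETER)
                self.declare_math(math)
                kind = "assignment" if name == "assignmentRule" else "rate"
                self.model.rules.append(Rule(kind, math=math, target_id=target))
            else:
                self.drop(name, "unsupported rule type")

    def import_constraints(self, mel) -> None:
        lst = _child(mel, self.core, "listOfConstraints")
        for cel in _children(lst, self.core, "constraint"):
            math = self.math(cel, "constraint")
            if math is None:
                continue
            con = _constraint_from_math(math)
            if con is None:
                self.drop("constraint", "math is not a bound comparison "
                                        "or conjunction of two")
                continue
            declare(self.model, con.symbol_id, SymbolKind.PARAMETER)
            for bound in (con.lower, con.upper):
                if isinstance(bound, MathNode):
                    self.declare_math(bound)
            self.model.constraints.append(con)

    def import_events(self, mel) -> None:
        lst = _child(mel, self.core, "listOfEvents")
        for eel in _children(lst, self.core, "event"):
            eid = eel.get("id")
            if not eid:
                eid = f"_E{self._auto_event}"
                while eid in self.model.symbols:
                    self._auto_event += 1
                    eid = f"_E{self._auto_event}"
                self._auto_event += 1
            if _child(eel, self.core, "delay") is not None:
                self.drop("delay", f"event '{eid}' has a delay")
            trig_el = _child(eel, self.core, "trigger")
            trigger = self.math(trig_el, f"trigger of '{eid}'") \
                if trig_el is not None else None
            if trigger is None:
                self.drop("event", f"event '{eid}' has no usable trigger")
                continue
            ev = Event(id=eid, trigger=trigger)
            ev.persistent = trig_el.get("persistent", "true") == "true"
            ev.initial_value_trigger = trig_el.get("initialValue", "true") == "true"
            ev.use_values_from_trigger_time = \
                eel.get("useValuesFromTriggerTime", "true") == "true"
            pri_el = _child(eel, self.core, "priority")
            if pri_el is not None:
                ev.priority = self.math(pri_el, f"priority of '{eid}'")
                if ev.priority is not None:
                    self.declare_math(ev.priority)
            self.declare_math(trigger)
            asn_lst = _child(eel, self.core, "listOfEventAssignments")
            for ael in _children(asn_lst, self.core, "eventAssignment"):
                target = ael.get("variable", "")
                expr = self.math(ael, f"assignment in '{eid}'")
                if expr is None:
                    continue
                declare(self.model, target, SymbolKind.PARAMETER)
                self.declare_math(expr)
                ev.assignments.append((target, expr))
            if not ev.assignments:
                self.drop("event", f"event '{eid}' has no usable assignments")
                continue
            declare(self.model, eid, SymbolKind.EVENT, explicit=True)
            self.model.events.append(ev)

    def import_objectives(self, mel) -> None:
        lst = _child(mel, FBC_NS, "listOfObjectives")
        if lst is None:
            return
        active = lst.get(f"{{{FBC_NS}}}activeObjective", "")
        objectives: list[tuple[str, Objective]] = []
        for oel in _children(lst, FBC_NS, "objective"):
            sense = oel.get(f"{{{FBC_NS}}}type", "maximize")
            obj = Objective(sense=sense)
            flx_lst = _child(oel, FBC_NS, "listOfFluxObjectives")
            for fel in _children(flx_lst, FBC_NS, "fluxObjective"):
                rid = fel.get(f"{{{FBC_NS}}}reaction", "")
                coeff = _parse_sbml_number(
                    fel.get(f"{{{FBC_NS}}}coefficient", "1"))
                declare(self.model, rid, SymbolKind.PARAMETER)
                obj.terms.append((coeff, rid))
            objectives.append((oel.get(f"{{{FBC_NS}}}id", ""), obj))
        # the model's first objective is the active one
        objectives.sort(key=lambda pair: pair[0] != active)
        self.model.objectives.extend(obj for _, obj in objectives)

    def import_layout(self, mel) -> None:
        lst = _child(mel, LAYOUT_NS, "listOfLayouts")
        if lst is None:
            return
        layouts = _children(lst, LAYOUT_NS, "layout")
        if not layouts:
            return
        if len(layouts) > 1:
            self.drop("layout", "only the first layout is imported")
        lel = layouts[0]
        lay = self.model.layout
        lay.enabled = True
        ann = _child(lel, self.core, "annotation")
        if ann is not None:
            st = _child(ann, STYLE_NS, "styleTemplate")
            if st is not None and st.text:
                lay.style_template = st.text
        for glyph in lel.iter():
            if not isinstance(glyph.tag, str):
                continue
            name = _local(glyph)
            ref = None
            if name == "speciesGlyph":
                ref = glyph.get(f"{{{LAYOUT_NS}}}species")
            elif name == "compartmentGlyph":
                ref = glyph.get(f"{{{LAYOUT_NS}}}compartment")
            elif name == "reactionGlyph":
                ref = glyph.get(f"{{{LAYOUT_NS}}}reaction")
            elif name == "generalGlyph":
                ref = glyph.get(f"{{{LAYOUT_NS}}}reference")
            elif name == "textGlyph":
                self.drop("textGlyph", "text glyphs are not represented")
                continue
            if not ref:
                continue
            if ref not in self.model.symbols:
                declare(self.model, ref, SymbolKind.PARAMETER)
            bb = _child(glyph, LAYOUT_NS, "boundingBox")
            if bb is not None:
                pos = _child(bb, LAYOUT_NS, "position")
                dms = _child(bb, LAYOUT_NS, "dimensions")
                x = _parse_sbml_number(pos.get(f"{{{LAYOUT_NS}}}x", "0")) \
                    if pos is not None else 0.0
                y = _parse_sbml_number(pos.get(f"{{{LAYOUT_NS}}}y", "0")) \
                    if pos is not None else 0.0
                w = _parse_sbml_number(dms.get(f"{{{LAYOUT_NS}}}width", "0")) \
                    if dms is not None else 0.0
                h = _parse_sbml_number(dms.get(f"{{{LAYOUT_NS}}}height", "0")) \
                    if dms is not None else 0.0
                if (w, h) != (0.0, 0.0):
                    lay.sizes[ref] = (w, h)
                    if (x, y) != (0.0, 0.0):
                        lay.positions[ref] = (x, y)
                elif (x, y) != (0.0, 0.0):
                    lay.positions[ref] = (x, y)
            curve = _child(glyph, LAYOUT_NS, "curve")
            if curve is not None:
                points: list[tuple[float, float]] = []
                segs = _child(curve, LAYOUT_NS, "listOfCurveSegments")
                for seg in _children(segs, LAYOUT_NS, "curveSegment"):
                    start = _child(seg, LAYOUT_NS, "start")
                    end = _child(seg, LAYOUT_NS, "end")
                    if start is None or end is None:
                        continue
                    p1 = (_parse_sbml_number(start.get(f"{{{LAYOUT_NS}}}x", "0")),
                          _parse_sbml_number(start.get(f"{{{LAYOUT_NS}}}y", "0")))
                    p2 = (_parse_sbml_number(end.get(f"{{{LAYOUT_NS}}}x", "0")),
                          _parse_sbml_number(end.get(f"{{{LAYOUT_NS}}}y", "0")))
                    if not points:
                        points.append(p1)
                    points.append(p2)
                if points:
                    lay.reaction_curves[ref] = tuple(points)

    def elide_default_compartment(self) -> None:
        """Drop the auto-created default compartment added at export time."""
        entry = self.model.symbols.get(DEFAULT_COMPARTMENT)
        if entry is None or entry.kind is not SymbolKind.COMPARTMENT:
            return
        if entry.initial_value != 1:
            return
        referenced = any(
            DEFAULT_COMPARTMENT in mathexpr.free_symbols(n)
            for n in _all_math(self.model))
        referenced = referenced or any(
            DEFAULT_COMPARTMENT in coll for coll in (
                self.model.layout.positions, self.model.layout.sizes))
        referenced = referenced or any(
            a.element_id == DEFAULT_COMPARTMENT for a in self.model.annotations)
        referenced = referenced or any(
            n.element_id == DEFAULT_COMPARTMENT for n in self.model.notes)
        referenced = referenced or any(
            u.element_id == DEFAULT_COMPARTMENT for u in self.model.uncertainty)
        if referenced:
            return
        for sym in self.model.symbols.values():
            if sym.compartment == DEFAULT_COMPARTMENT:
                sym.compartment = None
        del self.model.symbols[DEFAULT_COMPARTMENT]

    def reconcile_constraints(self) -> None:
        """Constraints whose subject is a reaction become flux bounds."""
        kept = []
        for con in self.model.constraints:
            if self.model.kind_of(con.symbol_id) is SymbolKind.REACTION \
                    and isinstance(con.lower, (float, int, type(None))) \
                    and isinstance(con.upper, (float, int, type(None))):
                self.model.flux_bounds.append(FluxBoundSet(
                    reaction_id=con.symbol_id,
                    lower=-_math.inf if con.lower is None else float(con.lower),
                    upper=_math.inf if con.upper is None else float(con.upper)))
            else:
                kept.append(con)
        self.model.constraints = kept


def _constraint_from_math(math: MathNode) -> Constraint | None:
    from .mathexpr import BoolOp, Cmp, Neg

    def as_value(node: MathNode):
        if isinstance(node, Num):
            return node.value
        if isinstance(node, Neg) and isinstance(node.child, Num):
            return -node.child.value
        return node

    def split(cmp: Cmp):
        """Return (symbol, lower, strict) or (symbol, upper, strict)."""
        if cmp.op not in ("<", "<="):
            return None
        strict = cmp.op == "<"
        if isinstance(cmp.right, Sym) and not isinstance(cmp.left, Sym):
            return ("lower", cmp.right.id, as_value(cmp.left), strict)
        if isinstance(cmp.left, Sym) and not isinstance(cmp.right, Sym):
            return ("upper", cmp.left.id, as_value(cmp.right), strict)
        return None

    parts: list = []
    if isinstance(math, Cmp):
        parts = [split(math)]
    elif isinstance(math, BoolOp) and math.op == "and" and len(math.children) == 2 \
            and all(isinstance(c, Cmp) for c in math.children):
        parts = [split(c) for c in math.children]
    if not parts or any(p is None for p in parts):
        return None
    symbols = {p[1] for p in parts}
    if len(symbols) != 1:
        return None
    con = Constraint(symbol_id=symbols.pop())
    for side, _, value, strict in parts:
        if side == "lower":
            if con.lower is not None:
                return None
            con.lower, con.strict_lower = value, strict
        else:
            if con.upper is not None:
                return None
            con.upper, con.strict_upper = value, strict
    return con


def import_sbml(xml: str | bytes) -> ImportReport:
    """Read an SBML L3 document into a Model.

    Inverse of :func:`export_sbml` on the supported construct set.
    Unsupported constructs are listed in ``dropped``; a level other than 3
    raises :class:`SBMLImportError` naming the level.
    """
    return _Importer().run(xml)


# ===========================================================================
# Structural self-check
# ===========================================================================

def check_document(xml: str | bytes) -> list[Diagnostic]:
    """Structural sanity checks on an SBML document.

    Verifies namespace declarations against actual package use, model-wide
    id uniqueness, required Level-3 attributes (constant flags,
    boundaryCondition, compartment references), and csymbol definition
    URLs.  Problems are returned as diagnostics, not raised.
    """
    diags: list[Diagnostic] = []

    def err(msg: str) -> None:
        diags.append(Diagnostic("error", 1, msg))

    data = xml.encode() if isinstance(xml, str) else xml
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        return [Diagnostic("error", 1, f"not well-formed XML: {exc}")]
    if _local(root) != "sbml":
        return [Diagnostic("error", 1, "root element is not <sbml>")]
    core = _ns(root)
    if core not in (CORE_NS, CORE_NS_V1):
        err(f"unexpected core namespace {core!r}")
    if root.get("level") != "3":
        err(f"level attribute is {root.get('level')!r}, expected '3'")
    if root.get("version") is None:
        err("missing version attribute")

    declared = set((root.nsmap or {}).values())
    used_ns = set()
    for el in root.iter():
        if isinstance(el.tag, str):
            used_ns.add(_ns(el))
            for attr in el.attrib:
                if attr.startswith("{"):
                    used_ns.add(attr[1:].split("}")[0])
    for pkg in _KNOWN_PACKAGE_NS:
        if pkg in used_ns and pkg not in declared:
            err(f"package namespace {pkg} used but not declared on <sbml>")
        if pkg in declared and pkg not in used_ns:
            err(f"package namespace {pkg} declared but never used")

    mel = _child(root, core, "model")
    if mel is None:
        err("document has no <model> element")
        return diags

    ids: dict[str, str] = {}

    def register(el, what: str, attr: str = "id") -> None:
        eid = el.get(attr)
        if not eid:
            if what in ("compartment", "species", "parameter", "reaction"):
                err(f"{what} without an id")
            return
        if eid in ids:
            err(f"duplicate id '{eid}' ({ids[eid]} and {what})")
        else:
            ids[eid] = what

    compartment_ids = set()
    for cel in _children(_child(mel, core, "listOfCompartments"), core,
                         "compartment"):
        register(cel, "compartment")
        compartment_ids.add(cel.get("id"))
        if cel.get("constant") is None:
            err(f"compartment '{cel.get('id')}' missing constant attribute")
    for sel in _children(_child(mel, core, "listOfSpecies"), core, "species"):
        register(sel, "species")
        sid = sel.get("id")
        for attr in ("constant", "boundaryCondition", "hasOnlySubstanceUnits"):
            if sel.get(attr) is None:
                err(f"species '{sid}' missing {attr} attribute")
        comp = sel.get("compartment")
        if comp is None:
            err(f"species '{sid}' missing compartment attribute")
        elif comp not in compartment_ids:
            err(f"species '{sid}' references unknown compartment '{comp}'")
    for pel in _children(_child(mel, core, "listOfParameters"), core,
                         "parameter"):
        register(pel, "parameter")
        if pel.get("constant") is None:
            err(f"parameter '{pel.get('id')}' missing constant attribute")
    for rel in _children(_child(mel, core, "listOfReactions"), core, "reaction"):
        register(rel, "reaction")
        if rel.get("reversible") is None:
            err(f"reaction '{rel.get('id')}' missing reversible attribute")
        for tag in ("listOfReactants", "listOfProducts"):
            for sref in _children(_child(rel, core, tag), core,
                                  "speciesReference"):
                if sref.get("id"):
                    register(sref, "speciesReference")
                if sref.get("constant") is None:
                    err(f"speciesReference in '{rel.get('id')}' missing "
                        "constant attribute")
    for eel in _children(_child(mel, core, "listOfEvents"), core, "event"):
        register(eel, "event")

    known_urls = {mathexpr.TIME_URL, mathexpr.RATEOF_URL}
    for cs in root.iter(f"{{{MATHML_NS}}}csymbol"):
        url = cs.get("definitionURL", "")
        if url in known_urls:
            continue
        if url.startswith(mathexpr.DISTRIB_URL_PREFIX) and \
                url[len(mathexpr.DISTRIB_URL_PREFIX):] in mathexpr.DRAW_FUNCTIONS:
            continue
        err(f"unknown csymbol definition URL {url!r}")

    return diags
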