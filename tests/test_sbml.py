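"""SBML export/import: mapping contract, round trips, structural checks."""

import re

import pytest
from lxml import etree

from rxnscript import (
    Model, SBMLImportError, check_document, export_sbml, import_sbml,
    parse_document, semantic_equal, serialize_model,
)
from rxnscript.mathexpr import Call, Num
from rxnscript.sbml import CORE_NS, DISTRIB_NS, FBC_NS, LAYOUT_NS


def _model(text: str) -> Model:
    m, diags = parse_document(text)
    assert not [d for d in diags if d.severity == "error"], diags
    return m


# ---------------------------------------------------------------------------
# export mapping contract
# ---------------------------------------------------------------------------

def test_empty_model_is_minimal_core_document():
    rep = export_sbml(Model(id="m"))
    assert rep.packages_used == set()
    root = etree.fromstring(rep.document.encode())
    assert root.nsmap == {None: CORE_NS}
    assert root.get("level") == "3" and root.get("version") == "2"


def test_flux_bounds_become_constant_parameters():
    rep = export_sbml(_model("R1: A -> B\n0 <= R1 <= 1000"))
    assert rep.packages_used == {"fbc"}
    root = etree.fromstring(rep.document.encode())
    params = {p.get("id"): p for p in root.iter(f"{{{CORE_NS}}}parameter")}
    assert params["R1_lb"].get("value") == "0"
    assert params["R1_ub"].get("value") == "1000"
    assert params["R1_lb"].get("constant") == "true"
    (rxn,) = root.iter(f"{{{CORE_NS}}}reaction")
    assert rxn.get(f"{{{FBC_NS}}}lowerFluxBound") == "R1_lb"
    assert rxn.get(f"{{{FBC_NS}}}upperFluxBound") == "R1_ub"


def test_uncertainty_mean_maps_to_distrib():
    rep = export_sbml(_model("x = 1\nx.mean = 10"))
    assert rep.packages_used == {"distrib"}
    root = etree.fromstring(rep.document.encode())
    (par,) = root.iter(f"{{{DISTRIB_NS}}}uncertParameter")
    assert par.get(f"{{{DISTRIB_NS}}}type") == "mean"
    assert par.get(f"{{{DISTRIB_NS}}}value") == "10"


def test_substance_only_species_use_amount_slot():
    rep = export_sbml(_model("substanceOnly S1\nS1 = 10\nS1 -> ; k*S1"))
    root = etree.fromstring(rep.document.encode())
    (sp,) = root.iter(f"{{{CORE_NS}}}species")
    assert sp.get("hasOnlySubstanceUnits") == "true"
    assert sp.get("initialAmount") == "10"
    assert sp.get("initialConcentration") is None
    rep2 = export_sbml(_model("S1 = 10\nS1 -> ; k*S1"))
    (sp2,) = etree.fromstring(rep2.document.encode()).iter(f"{{{CORE_NS}}}species")
    assert sp2.get("initialConcentration") == "10"


def test_default_compartment_added_and_elided():
    rep = export_sbml(_model("A -> B"))
    root = etree.fromstring(rep.document.encode())
    (comp,) = root.iter(f"{{{CORE_NS}}}compartment")
    assert comp.get("id") == "default_compartment" and comp.get("size") == "1"
    back = import_sbml(rep.document)
    assert "default_compartment" not in back.model.symbols
    assert back.model.symbols["A"].compartment is None


def test_named_stoichiometry_is_identified_species_reference():
    rep = export_sbml(_model("J0: n L -> RL; k*L^n\nn = 3"))
    root = etree.fromstring(rep.document.encode())
    srefs = {s.get("species"): s for s in root.iter(f"{{{CORE_NS}}}speciesReference")}
    assert srefs["L"].get("id") == "n"
    assert srefs["L"].get("constant") == "false"
    assert srefs["L"].get("stoichiometry") is None
    (ia,) = root.iter(f"{{{CORE_NS}}}initialAssignment")
    assert ia.get("symbol") == "n"


def test_constraint_math_is_conjunction_preserving_strictness():
    rep = export_sbml(_model("10 < J2 <= 50"))
    doc = rep.document
    assert "<and/>" in doc and "<lt/>" in doc and "<leq/>" in doc
    back = import_sbml(doc).model
    (con,) = back.constraints
    assert (con.lower, con.upper) == (10.0, 50.0)
    assert con.strict_lower and not con.strict_upper


def test_notes_wrap_markdown_verbatim():
    md = "Heading **bold** `code`"
    rep = export_sbml(_model(f'model notes "{md}"'))
    assert f"<pre>{md}</pre>" in rep.document
    back = import_sbml(rep.document).model
    assert back.notes[0].markdown == md


def test_annotations_use_qualifier_namespaces():
    m = _model('S1 -> ; k\nS1 is "urn:x:1"\nmodel isDescribedBy "urn:x:2"')
    doc = export_sbml(m).document
    assert "biology-qualifiers" in doc and "model-qualifiers" in doc
    back = import_sbml(doc).model
    got = {(a.element_id, a.qualifier, a.uri) for a in back.annotations}
    assert got == {("S1", "is", "urn:x:1"), ("model", "isDescribedBy", "urn:x:2")}


def test_export_is_deterministic(small_corpus):
    for text in small_corpus[:6]:
        m = _model(text)
        assert export_sbml(m).document == export_sbml(m).document


# ---------------------------------------------------------------------------
# import specifics
# ---------------------------------------------------------------------------

def test_import_export_roundtrip(small_corpus):
    for text in small_corpus:
        m = _model(text)
        rep = export_sbml(m)
        back = import_sbml(rep.document)
        assert back.dropped == [], (text, back.dropped)
        equal, diffs = semantic_equal(m, back.model)
        assert equal, (text, diffs)


def test_unknown_package_namespace_is_dropped_not_fatal():
    doc = export_sbml(_model("A -> B")).document
    doc = doc.replace(
        f'xmlns="{CORE_NS}"',
        f'xmlns="{CORE_NS}" xmlns:mystery="http://example.org/mystery/v1"')
    back = import_sbml(doc)
    assert len(back.model.reactions) == 1
    assert any("mystery" in c for c, _ in back.dropped)


def test_event_priority_uniform_csymbol_imported():
    text = "E1: at time > 2 and x < 1, priority = uniform(0,2): x = 5"
    doc = export_sbml(_model(text)).document
    (ev,) = import_sbml(doc).model.events
    assert ev.priority == Call("uniform", (Num(0), Num(2)))


def test_import_rejects_level_2():
    xml = ('<sbml xmlns="http://www.sbml.org/sbml/level2/version4" '
           'level="2" version="4"><model id="m"/></sbml>')
    with pytest.raises(SBMLImportError, match="level 2"):
        import_sbml(xml)


def test_import_rejects_non_sbml():
    with pytest.raises(SBMLImportError):
        import_sbml("<notsbml/>")
    with pytest.raises(SBMLImportError):
        import_sbml("plain text")


def test_unsupported_constructs_are_recorded():
    doc = export_sbml(_model("A -> B; k*A")).document
    # splice in a unit definition list
    doc = doc.replace("<listOfCompartments>",
                      "<listOfUnitDefinitions/><listOfCompartments>")
    back = import_sbml(doc)
    assert any(c == "listOfUnitDefinitions" for c, _ in back.dropped)


def test_piecewise_math_is_dropped_with_reason():
    doc = export_sbml(_model("A -> B; k*A")).document
    doc = re.sub(
        r"<math [^>]*>.*?</math>",
        '<math xmlns="http://www.w3.org/1998/Math/MathML">'
        "<piecewise><piece><cn>1</cn><true/></piece></piecewise></math>",
        doc, flags=re.S)
    back = import_sbml(doc)
    assert any("piecewise" in r for _, r in back.dropped)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def test_layout_coordinates_roundtrip():
    text = ("A -> B\nmodel.layout = on\n"
            "A.position = {50, 40}\nA.size = {80, 40}\n"
            "B.position = {200, 40}\nB.size = {80, 40}\n"
            '_J0.centroid = {125, 60}\n_J0.curvePoints = {90, 60, 160, 60}\n'
            'model.styleTemplate = "Escher"')
    m = _model(text)
    rep = export_sbml(m)
    assert rep.packages_used == {"layout"}
    root = etree.fromstring(rep.document.encode())
    glyphs = {g.get(f"{{{LAYOUT_NS}}}species"): g
              for g in root.iter(f"{{{LAYOUT_NS}}}speciesGlyph")}
    pos = glyphs["A"].find(f"{{{LAYOUT_NS}}}boundingBox/{{{LAYOUT_NS}}}position")
    assert pos.get(f"{{{LAYOUT_NS}}}x") == "50"
    back = import_sbml(rep.document)
    assert back.dropped == []
    equal, diffs = semantic_equal(m, back.model)
    assert equal, diffs


def test_fallback_grid_layout_is_deterministic_and_stable():
    """`model.layout = on` with no coordinates places species on a grid."""
    m = _model("A -> B\nB -> C\nmodel.layout = on")
    doc1 = export_sbml(m).document
    doc2 = export_sbml(m).document
    assert doc1 == doc2
    gen1 = import_sbml(doc1).model
    assert gen1.layout.positions["A"] == (50.0, 50.0)
    assert gen1.layout.positions["B"] == (200.0, 50.0)
    assert gen1.layout.sizes["A"] == (80.0, 40.0)
    # from the second generation on the trip is the identity
    gen2 = import_sbml(export_sbml(gen1).document).model
    equal, diffs = semantic_equal(gen1, gen2)
    assert equal, diffs
    assert serialize_model(gen1) == serialize_model(gen2)


# ---------------------------------------------------------------------------
# check_document
# ---------------------------------------------------------------------------

def test_check_document_clean_on_exports(small_corpus):
    for text in small_corpus[:20]:
        doc = export_sbml(_model(text)).document
        assert check_document(doc) == [], text


def test_check_document_missing_species_compartment():
    doc = export_sbml(_model("A -> B")).document
    broken = doc.replace(' compartment="default_compartment"', "", 1)
    diags = check_document(broken)
    assert sum(1 for d in diags if "compartment" in d.message) == 1


def test_check_document_duplicate_id():
    doc = export_sbml(_model("A -> B\nk = 2")).document
    broken = doc.replace('parameter id="k"', 'parameter id="A"')
    assert any("duplicate id" in d.message for d in check_document(broken))


def test_check_document_namespace_mismatch():
    doc = export_sbml(_model("A -> B")).document
    # declare fbc without using it
    broken = doc.replace(f'xmlns="{CORE_NS}"',
                         f'xmlns="{CORE_NS}" xmlns:fbc="{FBC_NS}"')
    assert any("declared but never used" in d.message
               for d in check_document(broken))
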