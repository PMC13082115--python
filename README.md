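# rxnscript

A human-readable, plain-text language for biochemical reaction-network
models, with **lossless bidirectional translation to SBML Level 3
Version 2** — Core plus the Flux Balance Constraints (fbc), Distributions
(distrib) and Layout packages.

Systems biologists exchange models as SBML, but XML is painful to read,
write and diff by hand. `rxnscript` lets a modeler write

```text
S1 -> S2; k1*S1
```

and get a standards-compliant SBML document back — that single line
implicitly declares `S1` and `S2` as species (they appear on the reaction
sides) and `k1` as a parameter (it is referenced in the rate law).  The
same pipeline runs in reverse: any supported SBML L3 document becomes
canonical model text again, and `text → model → SBML → model → text` is
the identity on everything the language can express.

## The language in one screen

```text
J0: 2 A + n B -> C; k1*A^2*B^n   // reactions; named stoichiometry n
n = 3                            // initialization (also: draws, see below)
ka = lognormal(0.1, 0.25)        // initial assignment drawing from a distribution
E0: at time > 3: k4 = 10         // discrete event
E1: at time > 2, priority = uniform(0, 2): x = 5   // stochastic priority
x := rateOf(G)                   // assignment rule using the rateOf csymbol
G' = -0.1*G                      // rate rule
A1: 0 = S1 + S2 - Stot           // algebraic rule
10 < J2 < 50                     // parameter constraint (chained inequality)
0 <= J0 <= 1000                  // flux bounds (J0 is a reaction)
maximize J0                      // FBC objective
substanceOnly S1                 // species S1 is an amount, not a concentration
S1 is "http://identifiers.org/CHEBI:17234"   // CV-term annotation
model notes "Markdown **notes** travel verbatim."
model.layout = on                // diagram data (positions, sizes, curves)
x.position = {50, 40}
x.mean = 10                      // uncertainty metadata (distrib package)
```

Identifier kinds are inferred from the roles an id plays — reaction side
⇒ species, coefficient position ⇒ named stoichiometry, `in C` ⇒
compartment, anything first seen in math ⇒ parameter — deterministically
and independently of statement order.  Explicit declarations
(`const species $X in C1`) pin a kind; contradictions are diagnostics,
never crashes.

## Worked example

`demo.ant`:

```text
model uptake
  J0: Glc_ext -> Glc; vmax*Glc_ext/(km + Glc_ext)
  km = 0.5
  vmax = lognormal(0.1, 0.25)
  vmax.mean = 1.1
  0 <= J0 <= 1000
  maximize J0
end
```

```bash
$ rxnscript a2s demo.ant -o demo.xml     # text -> SBML
$ rxnscript s2a demo.xml                 # SBML -> canonical text
model uptake
  J0: Glc_ext -> Glc; vmax*Glc_ext/(km + Glc_ext)
  km = 0.5
  vmax = lognormal(0.1, 0.25)
  0 <= J0 <= 1000
  maximize J0
  vmax.mean = 1.1
end
$ rxnscript roundtrip demo.ant
round trip: PASS
```

The exported document declares exactly the namespaces it uses (here Core
+ fbc + distrib): the flux bounds become constant parameters `J0_lb = 0`
and `J0_ub = 1000` referenced from the reaction's fbc attributes, the
lognormal initializer becomes a distrib `csymbol` inside an initial
assignment, and `vmax.mean = 1.1` becomes a distrib `uncertParameter` of
type `mean` with value 1.1.

Distribution draws are evaluated with a seeded generator:

```bash
$ rxnscript sample "uniform(0, 2)" -n 100000 --seed 1
n = 100000
mean = 0.999989
sd = 0.577673
min = 1.54242e-06
max = 1.99998
```

— the sample mean sits at the analytic mean (0+2)/2 = 1.

As a library:

```python
from rxnscript import parse_document, export_sbml, import_sbml, serialize_model

model, diagnostics = parse_document("S1 -> S2; k1*S1")
xml = export_sbml(model).document
assert serialize_model(import_sbml(xml).model) == serialize_model(model)
```

## Scope

Submodel composition/namespacing, unit definitions, SBML Level 2 export,
Render-package drawing (the style-template name is stored pass-through),
and simulation (ODE/FBA solving) are out of scope — this package is a
translator, not a simulator.  See `docs/methods.md` for design notes and
known limitations.
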