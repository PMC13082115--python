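# Methods and design notes

## Architecture

The package is a three-stage translator with one hub data structure:

```
text  --parser-->  Model (internal representation)  --exporter-->  SBML
text  <--serializer--          Model                <--importer--  SBML
```

`Model` (in `rxnscript.model`) holds a single flat symbol table plus
typed statement records (reactions, events, rules, constraints, flux
bounds, objectives, annotations, notes, uncertainty statistics, layout).
Both front ends populate it and both back ends read it, so losslessness
reduces to two invertibility claims that the test suite checks as
properties: `parse ∘ serialize` and `import ∘ export` are the identity
under semantic equality.

## Implicit declaration and kind promotion

Every identifier has exactly one kind.  The promotion ladder is:

* first seen in math → **parameter** (the weakest kind);
* appearing on a reaction side → **species**;
* appearing in coefficient position → **stoichiometry**;
* appearing in an `in <id>` context → **compartment**;
* statement labels → **reaction**, **event**, **rule**.

A plain math reference never demotes an established kind, and promotions
away from an explicitly declared kind are conflicts.  Because promotion
depends only on the *set* of roles an id plays, the final kind is
independent of statement order; the parser re-examines chained
inequalities once the whole document is read so that
`0 <= R1 <= 1000` becomes a flux bound even when it precedes the
definition of `R1`.

## Canonical serialization

The serializer emits a fixed section order (header, compartments,
species, reactions, rules, initializations, events, constraints, flux
bounds, objectives, uncertainty, annotations, notes, layout) and sorts
statements within each section by identifier.  Sorting — rather than
preserving declaration order — makes the output a pure function of the
model's semantic content: any two semantically equal models serialize
byte-identically, serialization is a fixpoint after one parse/serialize
round, and canonical text diffs cleanly under version control.  The one
exception is objectives, whose declaration order is semantic (the first
objective is the active one) and is therefore preserved.  Comments are
dropped; numbers print as the shortest round-trip decimal with integral
values un-pointed.

## SBML mapping choices

Where SBML demands information the language does not carry, the mapping
pins a deterministic convention so round trips are exact:

* **Default compartment.**  SBML requires species to live in a
  compartment; the language does not.  Species without one are exported
  into an auto-created `default_compartment` of size 1, and the importer
  elides that compartment again when nothing else references it.  (A
  user model that genuinely declares a size-1 `default_compartment` that
  nothing but species reference is indistinguishable from the synthetic
  one and will be elided — a known corner.)
* **Reversibility.**  The arrow carries no reversibility marker, so all
  reactions export `reversible="true"`.
* **Event attributes.**  `persistent`, `initialValue` and
  `useValuesFromTriggerTime` default to true and have no surface syntax;
  imported non-default values are kept in the model (and survive SBML
  round trips) but cannot be re-expressed in text.
* **Constant flags.**  The `const` keyword maps 1:1 onto SBML's
  `constant` attribute in both directions; no inference is attempted.
* **Flux bounds** become constant parameters `<rid>_lb` / `<rid>_ub`
  (collisions resolved by numeric suffix); one-sided bounds use
  `INF`/`-INF`.  Strict flux-bound inequalities are demoted to
  non-strict with a warning, since fbc bounds are closed intervals.
* **Constraints** encode as the conjunction of at most two comparisons,
  `lt` vs `leq` preserving strictness.  The importer pattern-matches
  exactly that shape; constraint math in any other form is dropped with
  a reason.  A bound that is a *bare* identifier (rather than a number
  or a compound expression) is not reconstructable on import because
  the subject cannot be told from the bound.
* **Qualifier namespaces.**  Element-level CV terms use the biology-
  qualifier namespace, model-level ones the model-qualifier namespace,
  with the qualifier keyword as the local name.  `origin`, `created` and
  `creator` are carried in the same namespaces for uniformity.
* **Notes** embed the Markdown verbatim in an XHTML `<pre>` block; no
  Markdown→XHTML conversion is attempted (presentation concern).
* **Layout.**  Positions/sizes become glyph bounding boxes (species,
  compartment and reaction glyphs; general glyphs for anything else),
  curve point sequences become chains of line segments.  A glyph's
  missing half defaults to zeros; the importer treats a (0,0) size as
  absent, so an element positioned at exactly (0,0) with no size is the
  one un-representable corner.  The style-template name is pass-through
  text stored in a package-private annotation (`urn:rxnscript:...`) on
  the layout.
* **Fallback grid.**  `model.layout = on` with no coordinates places
  species boxes of 80×40 on a 150-unit pitch, four per row, row-major in
  id order.  This is a deliberately trivial stand-in for an auto-layout
  engine: it is deterministic, so the export is reproducible and the
  round trip is the identity from the second generation on (the first
  export necessarily *adds* the generated coordinates).

## Expressions

Trees cover numbers, symbol references, the `time` and `rateOf`
csymbols, arithmetic (`^` right-associative, unary minus binding between
`*` and `^`), comparisons, boolean connectives (`and/or/not`, with
`&&/||/!` accepted on input), a small set of 1:1 MathML functions
(`sin cos tan exp ln log10 sqrt abs floor ceiling`) and the distrib draw
functions with their two-parameter forms:

| draw | parameters | mean |
|---|---|---|
| `normal(mean, sd)` | sd > 0 | mean |
| `uniform(lo, hi)` | lo < hi | (lo+hi)/2 |
| `lognormal(mu, sigma)` | log-scale, sigma > 0 | exp(mu+sigma²/2) |
| `exponential(rate)` | rate > 0 | 1/rate |
| `gamma(shape, scale)` | both > 0 | shape·scale |
| `poisson(rate)` | rate ≥ 0 | rate |
| `binomial(n, p)` | integer n ≥ 0, p ∈ [0,1] | np |

`normal` takes a standard deviation (not a variance) and `lognormal`
log-scale parameters, matching the distrib csymbol call forms.
Evaluation is pure given a seed: draws consume a
`numpy.random.Generator`, comparisons/booleans return 1/0, and
domain violations (e.g. `uniform(2,1)`) raise rather than return junk.
`rateOf` and `time` have no value outside a simulator and are rejected
by the evaluator; `rateOf`'s argument must be a bare identifier.
Canonical rendering uses minimal parentheses while keeping the reparse
structurally identical (equal-precedence right children of
left-associative operators, and left children of `^`, stay fenced).

## Fixture generation and what it does (not) show

`GeneratorConfig` defaults to 6 species and 5 reactions — the size of a
typical hand-written pathway sketch — with every optional feature off;
tests switch features on explicitly and sweep seeds.  Generated rate
laws are mass-action-like with bounded expression depth (default 3),
coordinates are positive grid points, and URIs/notes avoid embedded
quotes so round trips stay byte-stable.  Passing the round-trip suite on
this corpus demonstrates that the *representable* feature lattice is
preserved; it says nothing about foreign SBML in the wild, which may use
constructs (units, function definitions, delays, piecewise math, other
packages) that the importer deliberately reports as dropped rather than
silently mangling.

## The priority race

Two simultaneous events with priorities drawn from `uniform(0,1)` and
`uniform(0,2)` order themselves stochastically.  With u₀ ~ U(0,1) and
u₁ ~ U(0,2) independent, P(u₁ < u₀) = P(u₁ < 1)·P(u₁ < u₀ | u₁ < 1)
= ½·½ = ¼, so the wide draw wins with probability ¾.
`priority_race(n, seed)` measures this by evaluating the two priority
expressions n times through the expression evaluator with a shared
seeded generator; at n = 10⁵ the estimate lands within one percentage
point of 75%.  `scripts/acceptance.py` reports both percentages.

## Numerical conventions

* Numbers serialize as shortest round-trip decimals (`repr`), integral
  values without a decimal point; SBML infinities as `INF`/`-INF`.
* `semantic_equal` compares math by canonical rendering and collections
  as order-insensitive multisets (objectives ordered, see above),
  reporting at most 20 differences.
* Diagnostics carry 1-based line numbers; the parser recovers at
  statement granularity and never raises on any byte input.

## Known limitations

* No submodels, units, `delay`, `piecewise`, function definitions, or
  Render encoding (all reported as dropped on import).
* Event attribute values other than the defaults are representable in
  the model and in SBML, but not in text.
* The corner cases noted above for `default_compartment` elision,
  bare-identifier constraint bounds, and (0,0)-positioned size-less
  layout glyphs.
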