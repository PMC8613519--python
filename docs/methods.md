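# Methods

This note records the data model, the algorithmic and numerical choices,
and the places where the design was genuinely open and we had to commit.

## Data model

**Term registry.**  All vocabulary lives in a `TermRegistry`: CURIE, IRI,
label, a coarse kind (`class`, `object-property`, `category`), and parent
links forming an acyclic hierarchy.  The fixture registry mints ~70 terms:
the anatomy/quality classes the worked examples need (keeping published
OBO-style identifiers where they exist, `EX:` elsewhere), the object
properties (*has part*, *bearer of*, *has component*, *inheres in*,
*increased in magnitude relative to*, plus the two deliberately non-DL
properties *has not part any* and *towards class*), unit terms under a
common `EX:unit` parent, and the perceptual-category terms.  Perceptual
categories are ordinary registry terms rather than an enum because the set
of observational questions (weight, length, volume, position, color,
shape, function, development, plus parthood and instantiation) is a
domain-ontology concern users must be able to extend; the three
measurement categories sit under a `measurement` parent so data views can
select "all measurements" via the subclass closure.  No published property
IRIs are asserted for the parthood/quality relations — the choice between
the candidate upper-ontology variants is not ours to make — so the fixture
mints its own and documents that assumption here.

**Class expressions.**  The Manchester subset is `atomic`, n-ary `and`,
unary `not`, `property some filler`, `property exactly n filler`, with
parentheses.  `min`/`max`/`only`/`value`/`or` are rejected with an
explicit error: phenotype class axioms in practice do not use them, and a
silent partial parse would be worse than a loud refusal.  Tokenization is
registry-driven: labels (multi-word, digit-bearing) are matched
longest-first; keywords win over labels; matching is case-sensitive.

**Canonical form.**  `and` nodes are flattened and their operands sorted
by a registry-free structural key (kind, CURIE, cardinality, recursive),
giving a canonical representative per intersection.  Sorting by a
structural key rather than by serialized label text keeps canonicalization
independent of the registry and stable under label edits.  Duplicate
operands are *kept*: `A ⊓ A` is logically `A`, but collapsing duplicates
would silently change witness counts when an expression is instantiated,
and we prefer the conversion layer to be count-faithful.  With this,
`parse(serialize(e)) = e` for every canonical tree and
`serialize(parse(t)) = t` for every canonical text — both property-tested.

**EQ statements.**  `EQStatement` carries entity, optional quality,
optional attribute, and the two extensions: related entity (relational
qualities) and count (quantitative statements), the latter two mutually
exclusive.  The attribute survives from the older entity–attribute–value
form; since quality ontologies organize values under attribute parents,
a valid attribute must subsume the quality, and the inversion uses exactly
that fact (ancestor = attribute, descendant = quality) to decompose a
two-quality conjunction.  Hierarchically unrelated multi-quality
conjunctions are rejected as not-representable rather than guessed at.
Nested EQ statements (composite characters) are not modelled as statement
trees; anything deeper than one level stays in class-expression form.
The relating property of the related-entity scheme is a parameter
defaulting to *increased in magnitude relative to* — the one relational
construct the worked examples exercise — because hard-wiring a "towards"
semantics would be an invention.  Counts compile to
`has component exactly C E`, reusing the one count construct the worked examples exercise.

## Instance graphs and fragmentation

Every instance is minted with its own URI; blank nodes never appear at the
instance level (that anonymity is precisely the weakness of the
class-based form).  URI minting is deterministic from (namespace, seed,
insertion counter) so identical build scripts give byte-identical
canonical Turtle; a seeded UUID-style policy exists for users who prefer
opaque URIs.  The parthood backbone is a strict tree (single parent,
acyclic by construction); shared parts (a DAG partonomy) are a documented
extension point, not supported in v1.  Measurements are a minted
measurement-quality instance carrying a decimal value (`decimal.Decimal`,
so `84.3` round-trips exactly) and a unit term.

Fragmentation produces exactly one named graph per descriptive assertion
(parthood, quality, measurement).  Placement policy for type/label
triples: a minted instance's `type`/`label` triples live in the named
graph of the assertion that minted it, so each graph is self-describing;
the ODU's own live in a dedicated instantiation graph.  Under this policy
fragmentation is a *strict* partition (pairwise disjoint graphs), and
`union(fragment(pkg))` equals the description's triple set exactly —
property-tested over 200 random graphs.  The triple typing a named graph
with its category class is emitted in the TriG default graph, outside the
named graph, to keep that identity exact.  Named-graph URIs are
deterministic in (description URI, category, subject part, ordinal).

Metadata uses a small fixture vocabulary (agent, date, source, instrument,
free fields); mapping to standard provenance ontologies is a serialization
option, not core semantics.  Micro-publication payloads (prose, media
links) ride in the reserved free fields `text` and `media`.
Nanopublications follow the conventional four-graph layout
(head/assertion/provenance/pubinfo); export requires at least one metadata
record because a nanopublication without provenance is meaningless.
Revisions keep the description URI stable and swap the graph membership:
the replacement must share the superseded graph's category, the superseded
graph stays in history behind a `supersedes` link documented in RDF, and
revising an already-superseded graph is a staleness error.  Queries and
views run over active graphs only, matching the correction workflow where
the fixed value replaces the erroneous one.

## Conversion

**Expansion (TBox → ABox).**  Skolemized existential instantiation:
`some` mints exactly one witness — the minimal-model reading; the worked
axiom pairs `exactly` with exact instance counts and gives no policy for
bare `some`, so one witness is the least commitment.  `exactly n` mints
`n` witnesses and records a hybrid exact-count pattern (the closure would
otherwise be lost under the open-world assumption); `not` mints nothing
and records a hybrid absence pattern; restrictions over properties other
than the part/quality properties go to a residue list with a reason.
Expansion is total — the result always partitions the input into minted
structure, hybrid patterns, and residue.  Quality restrictions nested
inside an `exactly` filler are instantiated once per witness: each witness
gets its own quality instance.  Hybrid phenotype classes get URIs minted
from a hash of their canonical serialization, so identical patterns unify
across descriptions.

**Roll-up (ABox → TBox).**  The implicit class expression a description
shortens: the conjunction of the root's classes with `has part some
<subtree>` per child and `bearer of some <class>` per quality.  Under
`closed_world`, sibling parts whose rolled-up subtrees are identical are
*grouped* into a single `has part exactly n <subtree>` restriction
(replacing, not supplementing, their existentials): the worked axiom
writes `has part exactly 2 antenna` with no accompanying existential, and
replacing keeps expansion and roll-up mutually inverse — emitting both
forms would double-mint witnesses on re-expansion.  With that choice,
`expand(rollup(pkg))` is graph-isomorphic to `pkg` up to URI renaming for
measurement-free descriptions (property-tested, 100 seeds).  Measurements
are never rolled up; they are reported in a skip list, because compiling
numeric data into class axioms requires a phenotype class per value
combination — the documented failure mode of the class-based form — and
inventing value-partition classes would paper over it.

**Absence / exact count.**  Both constructs come in two variants: an
ABox-only encoding using the non-DL properties (*has not part any*,
*towards class* with a count-quality instance), flagged non-compliant, and
a hybrid encoding asserting a minted phenotype class whose axiom is
`not (has part some X)` / `has component exactly n X`, flagged compliant.
The compliance checker detects exactly the non-DL property usages, so the
builders' flags and the checker agree by construction and by test.
Cardinality 0 is accepted and is intentionally *not* equated with absence
by the code — that equivalence is a reasoning step, and this package does
no reasoning.

**Comparatives.**  `increased`/`decreased` relative to a known reference
value become exclusive lower/upper bounds with the unit carried through;
without the reference value the conversion raises — a comparative
description alone carries no usable magnitude.

## Validation and querying

Well-formedness checks report (never raise): classless instances, blank or
relative URIs, multi-parent or cyclic parthood, unitless measurements as
errors; missing labels on anatomical-entity instances as warnings.  The
content standard is data: a YAML catalog of shape templates (category →
required roles → value constraints), with a default catalog covering
parthood, instantiation, shape, color, and the three measurement
categories.  Role binding is a plain triple-pattern scan; a SHACL export
exists for interoperability, but validation always runs on the internal
engine.  Querying is conjunctive ABox pattern matching with optional
subclass closure — deliberately no entailment regime, mirroring the
computational argument for the instance-based form.  There is **no unit
conversion**: a milligram criterion never matches a millimetre (or gram)
measurement.  Silent conversion without a unit ontology risks wrong
matches; the limitation is stated loudly instead.  The taxon criterion is
matched as a class assertion on the ODU, the narrowest reading that needs
no taxonomy model.

## Synthetic data

The generator draws a partonomy of depth ≤ 3 and branching ≤ 2 by default,
with per-node quality probability 0.4 and measurement probability 0.3,
values uniform over per-kind ranges (live weight 1–200 mg, length
0.5–30 mm) rounded to one decimal — the precision of the worked
measurements.  Defaults were chosen once to give descriptions of roughly
the worked examples' size (a handful of parts, a few observations) with
all assertion kinds regularly exercised.  The PRNG is Python's Mersenne
Twister seeded explicitly; no iteration-order nondeterminism enters the
output, so re-runs are byte-identical across platforms.  What the
generator emulates is *structure* — partonomy shape, category tagging,
measurement typing — not real anatomy: class choices are uniform and
independent, so passing tests demonstrate the machinery (fragmentation
identities, round trips, validation contracts) on arbitrary well-formed
descriptions, not statistical fidelity to real specimens.  Property
suites run at 100–200 seeded cases; the acceptance script uses 100
random descriptions for the structural invariants, sized to keep the
whole run in seconds.

## Known limitations

* No DL reasoning, no entailment-regime querying, no SPARQL endpoint —
  out of scope by design.
* Single-parent partonomies only; no spatial/positional geometry model;
  frames of reference beyond category tagging are not modelled.
* Unit criteria require exact unit identity (no conversion).
* EQ inversion needs the registry to split quality from attribute; without
  it, two-quality conjunctions are rejected as ambiguous.
* Nanopublications are not cryptographically signed or hashed.
* Store persistence round-trips graphs, membership, supersession, and
  metadata records, but not the minted metadata-graph URIs themselves.
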