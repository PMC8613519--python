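# phenokg

Tooling for representing empirical phenotype descriptions as semantic
graphs, built around the contrast between two modelling styles:

* **Class-based (TBox) form** — a *semantic phenotype*: the description
  lives inside the axiom of a phenotype ontology class, composed from
  entity–quality (EQ) statements in OWL Manchester syntax, e.g.
  `has part some (eye and (bearer of some red))`.  Compact, but every
  entity and quality inside the axiom is an anonymous resource.
* **Instance-based (ABox) form** — a *phenotype knowledge graph* (PKG):
  every part, quality, and measurement of the described specimen (the
  *operational descriptive unit*, ODU) is an instance with its own URI,
  organized along a parthood backbone.  Each descriptive statement — one
  parthood link, one shape, one weight measurement — becomes its own
  *named graph*, so single observations can carry metadata, be published
  as nanopublications, be corrected with full revision history, and be
  selected into data views.

The package is aimed at researchers and tool builders in phenomics and
morphology who want to produce, convert, validate, and query such
descriptions without standing up a triple store: it ships a fixture term
registry (standing in for the anatomy/quality ontologies, with the
familiar identifiers `UBERON:0000972` *antenna*, `PATO:0002254`
*flattened*, `MA:0000261` *eye*, …), a Manchester-subset parser, a
deterministic PKG builder, bidirectional TBox↔ABox conversion with
explicit handling of absences (`not (has part some ovipositor)`) and exact
counts (`has component exactly 3 ocellus`) under the open-world
assumption, a shape-template content standard, and criteria-based querying.

## Worked example

```python
from phenokg import *

reg = build_fixture_registry()

# Instance-based description: organism → head → antenna, with a flattened
# shape and a measured live weight of 84.3 mg on the organism.
pkg = create_description(reg, "EX:multicellular-organism",
                         minting=MintingPolicy(seed=1))
head = pkg.add_part(pkg.odu_uri, "UBERON:6000004")
pkg.add_part(head, "UBERON:0000972")
pkg.add_quality(pkg.odu_uri, "PATO:0002254", "EX:shape")
pkg.add_measurement(pkg.odu_uri, "EX:live-weight", "84.3",
                    "EX:milligram", "EX:weight")

for g in fragment(pkg):
    print(g.category, len(g.triples))
```

prints one named graph per descriptive statement (plus the ODU's
instantiation graph):

```
EX:parthood 3
EX:parthood 3
EX:shape 2
EX:weight 4
EX:instantiation 2
```

Applying a weight data view over a store returns exactly the triples of
the weight-measurement graph — the `84.3` literal and its milligram unit:

```python
store = Store(reg)
desc = store.add_description(pkg)
store.apply_view(desc, DataView("weights", frozenset(["EX:weight"])))
```

Conversion works in both directions.  Skolemizing the class axiom of a
flattened insect head with exactly two antennae mints the matching
instances, and records the cardinality closure as a DL-compliant hybrid
pattern so the exact count survives the open-world assumption:

```python
expr = parse_manchester("insect head and ( bearer of some flattened ) "
                        "and ( has part exactly 2 antenna )", reg)
res = expand_to_abox(expr, reg, "UBERON:6000004")
# 1 insect head, 1 flattened quality, 2 antenna instances
# hybrid: ('exact-count', 'has part exactly 2 antenna')
```

Rolling the instance graph above back up (closed world) yields

```
multicellular organism and ( has part exactly 1 ( insect head and
( has part exactly 1 antenna ) ) ) and ( bearer of some flattened )
```

with the measurement reported in a skip list rather than compiled into the
class expression — folding numeric data into class axioms would need one
phenotype class per combination of values, which is precisely the
weakness of the class-based form that the instance-based form avoids.

A `phenokg` CLI wraps the same operations (`phenokg --help`):
`fixtures build`, `describe`, `fragment`, `union`, `view`, `expand`,
`rollup`, `absence`, `count`, `compare-to-direct`, `validate`, `query`,
`nanopub`, `generate`.

## Layout

| Module | Contents |
| --- | --- |
| `phenokg.vocab` | term registry, fixture mini-ontology, Turtle I/O |
| `phenokg.manchester` | class-expression trees, parser, serializer |
| `phenokg.eq` | EQ statements and their composition/inversion |
| `phenokg.pkg` | instance-graph builder (parts, qualities, measurements) |
| `phenokg.store` | named-graph fragmentation, views, metadata, nanopubs, revisions |
| `phenokg.convert` | TBox↔ABox expansion/roll-up, absence/count variants, comparatives |
| `phenokg.validate` | well-formedness, shape templates, DL compliance, querying |
| `phenokg.synth` | deterministic random generator, worked-example fixtures |
| `phenokg.cli` | command-line interface |

See `docs/methods.md` for the modelling decisions and their rationale.
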