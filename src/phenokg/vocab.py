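"""Term registry: the vocabulary layer shared by every other module.

A :class:`TermRegistry` holds :class:`OntologyTerm` records — CURIE, IRI,
human-readable label, a coarse term kind, and parent links forming a subclass
(or sub-property / sub-category) hierarchy.  It stands in for the domain
reference ontologies a production deployment would load (anatomy, quality,
and phenotype ontologies): the fixture registry built by
:func:`build_fixture_registry` mints a small but representative vocabulary of
anatomical entity classes, quality classes, object properties, unit terms,
and perceptual-category terms, keyed to the identifiers used throughout the
worked examples (e.g. ``UBERON:0000972`` *antenna*, ``PATO:0002254``
*flattened*, ``MA:0000261`` *eye*).

Perceptual categories are ordinary registry terms (``term_kind="category"``),
not a hard-coded enumeration: each one names the kind of observational
question a descriptive statement answers (What is the weight / shape / color
of this structure?  What is it part of?).  The measurement categories
(weight, length, volume) sit under a common ``measurement`` parent so that
data views can select "all measurements" through the subclass closure.

The registry round-trips through Turtle (:meth:`TermRegistry.to_turtle` /
:meth:`TermRegistry.from_turtle`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import DomainError, UnknownTermError

# Fixture namespace for terms the cited ontologies do not provide.
EX_BASE = "https://example.org/phenokg/terms/"

DEFAULT_PREFIX_MAP: dict[str, str] = {
    "UBERON": "http://purl.obolibrary.org/obo/UBERON_",
    "PATO": "http://purl.obolibrary.org/obo/PATO_",
    "MA": "http://purl.obolibrary.org/obo/MA_",
    "MP": "http://purl.obolibrary.org/obo/MP_",
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "EX": EX_BASE,
}

_CURIE_RE = re.compile(r"^([A-Za-z][\w.-]*):([\w.-]+(?: [\w.-]+)*)$")

# Schema vocabulary used only in the registry's own Turtle encoding.
_SCHEMA = Namespace(EX_BASE + "schema/")
_KIND_CLASS = {"class": OWL.Class, "object-property": OWL.ObjectProperty,
               "category": _SCHEMA.PerceptualCategory}
_CLASS_KIND = {v: k for k, v in _KIND_CLASS.items()}

TERM_KINDS = frozenset(_KIND_CLASS)

# Canonical CURIEs for the fixture properties, used across modules.
HAS_PART = "EX:has-part"
PART_OF = "EX:part-of"
BEARER_OF = "EX:bearer-of"
INHERES_IN = "EX:inheres-in"
HAS_COMPONENT = "EX:has-component"
INCREASED_RELATIVE_TO = "EX:increased-in-magnitude-relative-to"
HAS_NOT_PART_ANY = "EX:has-not-part-any"
TOWARDS_CLASS = "EX:towards-class"
HAS_VALUE = "EX:has-value"
HAS_UNIT = "EX:has-unit"
TYPE = "rdf:type"
LABEL = "rdfs:label"

# Canonical CURIEs for perceptual-category terms.
CAT_MEASUREMENT = "EX:measurement"
CAT_WEIGHT = "EX:weight"
CAT_LENGTH = "EX:length"
CAT_VOLUME = "EX:volume"
CAT_POSITION = "EX:position"
CAT_COLOR = "EX:color"
CAT_SHAPE = "EX:shape"
CAT_FUNCTION = "EX:function"
CAT_DEVELOPMENT = "EX:development"
CAT_PARTHOOD = "EX:parthood"
CAT_INSTANTIATION = "EX:instantiation"

ANATOMICAL_ENTITY = "UBERON:0001062"
UNIT = "EX:unit"


@dataclass(frozen=True)
class OntologyTerm:
    """A single vocabulary entry.

    ``parents`` reference CURIEs of the same ``term_kind``; for classes this
    is the subclass relation, for properties the sub-property relation, for
    categories the category taxonomy.  ``non_dl`` marks object properties
    that fall outside the OWL/description-logics syntax (instance-subject,
    class-object constructs such as *has not part any* and *towards class*).
    """

    curie: str
    uri: str
    label: str
    term_kind: str
    parents: frozenset[str] = frozenset()
    non_dl: bool = False

    def __post_init__(self):
        if not _CURIE_RE.match(self.curie):
            raise DomainError(f"malformed CURIE: {self.curie!r}")
        if not self.label:
            raise DomainError(f"term {self.curie} has an empty label")
        if self.term_kind not in TERM_KINDS:
            raise DomainError(f"unknown term kind: {self.term_kind!r}")


class TermRegistry:
    """CURIE-keyed term store with a subclass hierarchy.

    Lookup is by CURIE (:meth:`resolve`) or, for the Manchester tokenizer,
    by label (:meth:`by_label`; classes and object properties only —
    category terms never appear in class expressions, so a category may
    legally share a label with a class, e.g. the *color* quality class and
    the *color* perceptual category).
    """

    def __init__(self, prefix_map: dict[str, str] | None = None):
        self.prefix_map: dict[str, str] = dict(prefix_map or DEFAULT_PREFIX_MAP)
        self.terms: dict[str, OntologyTerm] = {}
        self.category_terms: set[str] = set()
        # maps a quality (sub)class to the perceptual category its
        # descendants report under; used by conversion when a category is
        # not given explicitly
        self.quality_category_map: dict[str, str] = {}
        self._label_index: dict[str, str] = {}

    # -- construction -----------------------------------------------------

    def uri_for(self, curie: str) -> str:
        m = _CURIE_RE.match(curie)
        if not m:
            raise DomainError(f"malformed CURIE: {curie!r}")
        prefix, local = m.groups()
        if prefix not in self.prefix_map:
            raise UnknownTermError(curie, f"unregistered prefix {prefix!r} in {curie!r}")
        return self.prefix_map[prefix] + local.replace(" ", "%20")

    def curie_for(self, uri: str) -> str:
        """Invert :meth:`uri_for`; longest-prefix match over the prefix map."""
        best = None
        for prefix, base in self.prefix_map.items():
            if uri.startswith(base) and (best is None or len(base) > len(self.prefix_map[best])):
                best = prefix
        if best is None:
            raise UnknownTermError(uri, f"no registered prefix covers {uri!r}")
        return f"{best}:{uri[len(self.prefix_map[best]):].replace('%20', ' ')}"

    def add(self, curie: str, label: str, term_kind: str = "class",
            parents: tuple[str, ...] = (), non_dl: bool = False) -> OntologyTerm:
        if curie in self.terms:
            raise DomainError(f"duplicate CURIE: {curie}")
        term = OntologyTerm(curie=curie, uri=self.uri_for(curie), label=label,
                            term_kind=term_kind, parents=frozenset(parents),
                            non_dl=non_dl)
        self.terms[curie] = term
        if term_kind == "category":
            self.category_terms.add(curie)
        else:
            if label in self._label_index:
                raise DomainError(
                    f"label {label!r} already names {self._label_index[label]}")
            self._label_index[label] = curie
        return term

    def validate(self) -> None:
        """Check referential integrity and acyclicity of the parent graph."""
        g = nx.DiGraph()
        for term in self.terms.values():
            g.add_node(term.curie)
            for p in term.parents:
                if p not in self.terms:
                    raise UnknownTermError(p, f"{term.curie} references unknown parent {p}")
                if self.terms[p].term_kind != term.term_kind:
                    raise DomainError(
                        f"{term.curie} ({term.term_kind}) has parent {p} of kind "
                        f"{self.terms[p].term_kind}")
                g.add_edge(term.curie, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DomainError(f"cyclic hierarchy: {cycle}")

    # -- lookup -----------------------------------------------------------

    def resolve(self, curie: str) -> OntologyTerm:
        try:
            return self.terms[curie]
        except KeyError:
            raise UnknownTermError(curie) from None

    def __contains__(self, curie: str) -> bool:
        return curie in self.terms

    def label_of(self, curie: str) -> str:
        return self.resolve(curie).label

    def by_label(self, label: str) -> OntologyTerm:
        try:
            return self.terms[self._label_index[label]]
        except KeyError:
            raise UnknownTermError(label) from None

    def labels(self) -> list[str]:
        """All class / object-property labels, longest first (tokenizer order)."""
        return sorted(self._label_index, key=len, reverse=True)

    def uriref(self, curie: str) -> URIRef:
        return URIRef(self.resolve(curie).uri)

    # -- hierarchy --------------------------------------------------------

    def children_of(self, curie: str) -> set[str]:
        return {t.curie for t in self.terms.values() if curie in t.parents}

    def subclass_closure(self, curie: str) -> set[str]:
        """The term plus all its descendants (reflexive-transitive)."""
        self.resolve(curie)
        out = {curie}
        frontier = [curie]
        while frontier:
            nxt = self.children_of(frontier.pop())
            frontier.extend(nxt - out)
            out |= nxt
        return out

    def ancestors(self, curie: str) -> set[str]:
        """Strict ancestors through the parents relation."""
        out: set[str] = set()
        frontier = list(self.resolve(curie).parents)
        while frontier:
            p = frontier.pop()
            if p not in out:
                out.add(p)
                frontier.extend(self.resolve(p).parents)
        return out

    def is_a(self, curie: str, ancestor: str) -> bool:
        return curie == ancestor or ancestor in self.ancestors(curie)

    def is_unit(self, curie: str) -> bool:
        return curie in self and self.is_a(curie, UNIT)

    def category_for_quality(self, curie: str) -> str | None:
        """Perceptual category a quality class reports under, if mapped."""
        for c in (curie, *sorted(self.ancestors(curie))):
            if c in self.quality_category_map:
                return self.quality_category_map[c]
        return None

    # -- Turtle I/O -------------------------------------------------------

    def to_turtle(self) -> str:
        """Deterministic Turtle encoding (prefix header + sorted triples)."""
        g = Graph()
        for term in self.terms.values():
            u = URIRef(term.uri)
            g.add((u, RDF.type, _KIND_CLASS[term.term_kind]))
            g.add((u, RDFS.label, Literal(term.label)))
            rel = RDFS.subPropertyOf if term.term_kind == "object-property" else RDFS.subClassOf
            for p in sorted(term.parents):
                g.add((u, rel, URIRef(self.uri_for(p))))
            if term.non_dl:
                g.add((u, _SCHEMA.nonDLConstruct, Literal(True)))
        for quality, category in self.quality_category_map.items():
            g.add((URIRef(self.uri_for(quality)), _SCHEMA.perceptualCategory,
                   URIRef(self.uri_for(category))))
        header = "".join(f"@prefix {p}: <{b}> .\n" for p, b in sorted(self.prefix_map.items()))
        body = "".join(sorted(
            line + "\n" for line in g.serialize(format="nt").splitlines() if line.strip()))
        return header + "\n" + body

    @classmethod
    def from_turtle(cls, text: str) -> "TermRegistry":
        g = Graph()
        g.parse(data=text, format="turtle")
        prefix_map = {p: str(b) for p, b in g.namespaces() if p in DEFAULT_PREFIX_MAP or
                      str(b).startswith(EX_BASE) or p.isupper()}
        reg = cls(prefix_map={**DEFAULT_PREFIX_MAP, **prefix_map})
        pending: list[tuple[str, str, str, tuple[str, ...], bool]] = []
        for s in sorted(set(g.subjects(RDF.type, None))):
            kind_uri = next(iter(g.objects(s, RDF.type)))
            if kind_uri not in _CLASS_KIND:
                continue
            kind = _CLASS_KIND[kind_uri]
            label = str(next(iter(g.objects(s, RDFS.label)), ""))
            rel = RDFS.subPropertyOf if kind == "object-property" else RDFS.subClassOf
            parents = tuple(sorted(reg.curie_for(str(o)) for o in g.objects(s, rel)))
            non_dl = (s, _SCHEMA.nonDLConstruct, Literal(True)) in g
            pending.append((reg.curie_for(str(s)), label, kind, parents, non_dl))
        for curie, label, kind, parents, non_dl in sorted(pending):
            reg.add(curie, label, kind, parents, non_dl=non_dl)
        for s, o in g.subject_objects(_SCHEMA.perceptualCategory):
            reg.quality_category_map[reg.curie_for(str(s))] = reg.curie_for(str(o))
        reg.validate()
        return reg


def build_fixture_registry() -> TermRegistry:
    """Build the fixture mini-ontology used throughout the package.

    Terms carrying published OBO-style identifiers keep them; everything the
    worked examples additionally need (ocellus, ovipositor, abdomen, the
    flagellomere series, units, properties, categories) is minted in the
    ``EX:`` fixture namespace.  Construction is deterministic: calling this
    twice yields registries whose Turtle encodings are byte-identical.
    """
    reg = TermRegistry()

    # perceptual categories (the observational questions a statement answers)
    reg.add(CAT_MEASUREMENT, "measurement", "category")
    for curie, label in [(CAT_WEIGHT, "weight"), (CAT_LENGTH, "length"),
                         (CAT_VOLUME, "volume")]:
        reg.add(curie, label, "category", (CAT_MEASUREMENT,))
    for curie, label in [(CAT_POSITION, "position"), (CAT_COLOR, "color"),
                         (CAT_SHAPE, "shape"), (CAT_FUNCTION, "function"),
                         (CAT_DEVELOPMENT, "development"), (CAT_PARTHOOD, "parthood"),
                         (CAT_INSTANTIATION, "instantiation")]:
        reg.add(curie, label, "category")

    # object properties
    for curie, label in [(HAS_PART, "has part"), (PART_OF, "part of"),
                         (BEARER_OF, "bearer of"), (INHERES_IN, "inheres in"),
                         (HAS_COMPONENT, "has component"),
                         (INCREASED_RELATIVE_TO, "increased in magnitude relative to"),
                         (HAS_VALUE, "has value"), (HAS_UNIT, "has unit"),
                         (TYPE, "type"), (LABEL, "label")]:
        reg.add(curie, label, "object-property")
    reg.add(HAS_NOT_PART_ANY, "has not part any", "object-property", non_dl=True)
    reg.add(TOWARDS_CLASS, "towards class", "object-property", non_dl=True)

    # quality classes
    reg.add("EX:quality", "quality")
    reg.add("PATO:0000020", "color", parents=("EX:quality",))
    reg.add("PATO:0000322", "red", parents=("PATO:0000020",))
    reg.add("EX:yellow", "yellow", parents=("PATO:0000020",))
    reg.add("EX:dark-brown", "dark brown", parents=("PATO:0000020",))
    reg.add("EX:light-brown", "light brown", parents=("PATO:0000020",))
    reg.add("EX:color-brightness", "color brightness", parents=("PATO:0000020",))
    reg.add("EX:shape-quality", "shape", parents=("EX:quality",))
    reg.add("PATO:0002254", "flattened", parents=("EX:shape-quality",))
    reg.add("EX:length-quality", "length", parents=("EX:quality",))
    reg.add("EX:live-weight", "live weight", parents=("EX:quality",))
    reg.add("EX:count-quality", "count", parents=("EX:quality",))
    reg.add("MP:0001259", "abnormal body weight", parents=("EX:quality",))

    # anatomical entity classes
    reg.add(ANATOMICAL_ENTITY, "anatomical entity")
    anatomy = [
        ("EX:multicellular-organism", "multicellular organism"),
        ("UBERON:6000004", "insect head"), ("UBERON:0000972", "antenna"),
        ("MA:0000261", "eye"), ("EX:head", "head"), ("EX:clypeus", "clypeus"),
        ("EX:mandible", "mandible"), ("EX:labial-palp", "labial palp"),
        ("EX:maxillary-palp", "maxillary palp"), ("EX:occiput", "occiput"),
        ("EX:pedicel", "pedicel"), ("EX:postgena", "postgena"),
        ("EX:scape", "scape"), ("EX:vertex", "vertex"),
        ("EX:ocellus", "ocellus"), ("EX:ovipositor", "ovipositor"),
        ("EX:abdomen", "abdomen"),
    ]
    ordinals = ["first", "second", "third", "fourth", "fifth", "sixth", "seventh",
                "eighth", "ninth", "tenth", "eleventh", "twelfth", "thirteenth"]
    anatomy += [(f"EX:flagellomere-{i + 1}", f"{name} flagellomere")
                for i, name in enumerate(ordinals)]
    anatomy.append(("EX:flagellomere-14", "flagellomere 14"))
    for curie, label in anatomy:
        reg.add(curie, label, parents=(ANATOMICAL_ENTITY,))

    # units
    reg.add(UNIT, "unit")
    reg.add("EX:milligram", "milligram", parents=(UNIT,))
    reg.add("EX:millimetre", "millimetre", parents=(UNIT,))

    # a taxon class for query scenarios (taxa are not anatomical entities)
    reg.add("EX:insecta", "Insecta")

    reg.quality_category_map.update({
        "PATO:0000020": CAT_COLOR,
        "EX:shape-quality": CAT_SHAPE,
        "EX:length-quality": CAT_LENGTH,
        "EX:live-weight": CAT_WEIGHT,
    })

    reg.validate()
    return reg
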