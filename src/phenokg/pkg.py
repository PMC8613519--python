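"""Instance-based (ABox) phenotype knowledge graphs.

A :class:`PhenotypeKnowledgeGraph` describes one Operational Descriptive
Unit (ODU) — the particular specimen or structure the description is about.
Every part, quality, and measurement is an *instance* with its own minted
URI (never a blank node) that instantiates an ontology class; parthood
assertions form a tree rooted at the ODU, and that partonomy is the
organizational backbone of the description.  Each assertion is tagged with
the perceptual category it answers (parthood, shape, color, weight, ...),
which later drives named-graph fragmentation and data views.

URI minting is deterministic: a :class:`MintingPolicy` derives URIs from
(namespace, seed, insertion counter), so identical operation sequences
yield byte-identical canonical serializations.  A UUID-style random policy
(:class:`RandomMintingPolicy`) is available when stable URIs are not
wanted; it is still seeded.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from decimal import Decimal, InvalidOperation

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS

from . import vocab
from .errors import DomainError, UnknownReferenceError
from .vocab import (ANATOMICAL_ENTITY, BEARER_OF, CAT_INSTANTIATION, CAT_PARTHOOD,
                    HAS_PART, HAS_UNIT, HAS_VALUE, TermRegistry)

DESCRIPTIVE_KINDS = ("parthood", "quality", "measurement")
ASSERTION_KINDS = DESCRIPTIVE_KINDS + ("instantiation", "labeling")


@dataclass
class MintingPolicy:
    """Deterministic URI minting from (namespace, seed, insertion counter)."""

    namespace: str = "https://example.org/phenokg/data/"
    seed: int = 0
    _counter: int = field(default=0, repr=False)

    def mint(self, hint: str = "i") -> str:
        self._counter += 1
        return f"{self.namespace}{self.seed}/{hint}-{self._counter:04d}"

    def clone(self) -> "MintingPolicy":
        return replace(self)


@dataclass
class RandomMintingPolicy(MintingPolicy):
    """UUID-style minting; random-looking but reproducible from the seed."""

    def __post_init__(self):
        self._rng = random.Random(self.seed)

    def mint(self, hint: str = "i") -> str:
        return f"{self.namespace}{self._rng.getrandbits(128):032x}"


@dataclass
class InstanceNode:
    """An individual with its own URI; instantiates ≥1 ontology class."""

    uri: str
    asserted_classes: list[str]
    label: str | None = None


@dataclass(frozen=True)
class Assertion:
    """One statement about instances.

    * ``parthood``: subject = whole, object = part
    * ``quality`` / ``measurement``: subject = bearer, object = the minted
      quality instance; measurements additionally carry ``value`` + ``unit``
    * ``instantiation``: subject instance, ``cls`` = the class CURIE
    * ``labeling``: subject instance, ``text`` = the label literal
    """

    kind: str
    subject: str
    object: str | None = None
    cls: str | None = None
    text: str | None = None
    value: Decimal | None = None
    unit: str | None = None
    category: str | None = None

    def __post_init__(self):
        if self.kind not in ASSERTION_KINDS:
            raise DomainError(f"unknown assertion kind {self.kind!r}")
        if self.kind == "measurement" and (self.value is None or self.unit is None):
            raise DomainError("measurement assertions carry both value and unit")
        if self.kind != "measurement" and (self.value is not None or self.unit is not None):
            raise DomainError(f"{self.kind} assertions carry neither value nor unit")


@dataclass
class PartonomyNode:
    uri: str
    classes: tuple[str, ...]
    label: str | None
    children: list["PartonomyNode"] = field(default_factory=list)


class PhenotypeKnowledgeGraph:
    """Mutable builder + container for one ODU's instance-based description."""

    def __init__(self, registry: TermRegistry, odu_uri: str,
                 minting: MintingPolicy):
        self.registry = registry
        self.odu_uri = odu_uri
        self.minting = minting
        self.instances: dict[str, InstanceNode] = {}
        self.assertions: list[Assertion] = []
        self._parent: dict[str, str] = {}  # part uri -> whole uri

    # -- internal helpers -------------------------------------------------

    def _require(self, uri: str) -> InstanceNode:
        try:
            return self.instances[uri]
        except KeyError:
            raise UnknownReferenceError(f"unknown instance URI {uri!r}") from None

    def _mint_instance(self, cls: str, label: str | None, hint: str) -> str:
        self.registry.resolve(cls)
        uri = self.minting.mint(hint)
        if uri in self.instances:  # pragma: no cover - policy contract
            raise DomainError(f"minting policy produced duplicate URI {uri}")
        self.instances[uri] = InstanceNode(uri=uri, asserted_classes=[cls], label=label)
        self.assertions.append(Assertion("instantiation", uri, cls=cls,
                                         category=CAT_INSTANTIATION))
        if label is not None:
            self.assertions.append(Assertion("labeling", uri, text=label,
                                             category=CAT_INSTANTIATION))
        return uri

    # -- construction operations ------------------------------------------

    def assert_class(self, uri: str, cls: str) -> None:
        """Add a further class assertion to an existing instance."""
        self.registry.resolve(cls)
        node = self._require(uri)
        if cls not in node.asserted_classes:
            node.asserted_classes.append(cls)
            self.assertions.append(Assertion("instantiation", uri, cls=cls,
                                             category=CAT_INSTANTIATION))

    def add_part(self, whole_uri: str, part_class: str, label: str | None = None) -> str:
        """Mint a new part instance under ``whole_uri``; returns its URI."""
        self._require(whole_uri)
        if label is None:
            label = self.registry.label_of(part_class)
        part_uri = self._mint_instance(part_class, label, "part")
        self._parent[part_uri] = whole_uri
        self.assertions.append(Assertion("parthood", whole_uri, object=part_uri,
                                         category=CAT_PARTHOOD))
        return part_uri

    def add_quality(self, bearer_uri: str, quality_class: str, category: str) -> str:
        """Mint a quality instance borne by ``bearer_uri``, tagged with a category."""
        self._require(bearer_uri)
        if category not in self.registry.category_terms:
            raise DomainError(f"{category} is not a perceptual-category term")
        quality_uri = self._mint_instance(quality_class, None, "quality")
        self.assertions.append(Assertion("quality", bearer_uri, object=quality_uri,
                                         category=category))
        return quality_uri

    def add_measurement(self, bearer_uri: str, kind_class: str, value,
                        unit: str, category: str) -> str:
        """Mint a measurement-quality instance with a numeric value and unit."""
        self._require(bearer_uri)
        try:
            dec = Decimal(str(value))
        except InvalidOperation:
            raise DomainError(f"non-numeric measurement value {value!r}") from None
        if not self.registry.is_unit(unit):
            raise DomainError(f"{unit} is not a unit term")
        if category not in self.registry.subclass_closure(vocab.CAT_MEASUREMENT):
            raise DomainError(f"{category} is not a measurement category")
        m_uri = self._mint_instance(kind_class, None, "measurement")
        self.assertions.append(Assertion("measurement", bearer_uri, object=m_uri,
                                         value=dec, unit=unit, category=category))
        return m_uri

    # -- views -------------------------------------------------------------

    def descriptive_assertions(self) -> list[Assertion]:
        return [a for a in self.assertions if a.kind in DESCRIPTIVE_KINDS]

    def parent_of(self, uri: str) -> str | None:
        return self._parent.get(uri)

    def partonomy_tree(self) -> PartonomyNode:
        """The parthood backbone, rooted at the ODU, children in insertion order."""
        involved = {self.odu_uri}
        for a in self.assertions:
            if a.kind == "parthood":
                involved.update((a.subject, a.object))
        nodes = {uri: PartonomyNode(uri, tuple(self.instances[uri].asserted_classes),
                                    self.instances[uri].label)
                 for uri in involved if uri in self.instances}
        for a in self.assertions:
            if a.kind == "parthood":
                nodes[a.subject].children.append(nodes[a.object])
        return nodes[self.odu_uri]

    def assertion_triples(self, a: Assertion) -> list[tuple[URIRef, URIRef, object]]:
        """The RDF triples carried by one assertion."""
        reg = self.registry
        s = URIRef(a.subject)
        if a.kind == "instantiation":
            return [(s, RDF.type, reg.uriref(a.cls))]
        if a.kind == "labeling":
            return [(s, RDFS.label, Literal(a.text))]
        if a.kind == "parthood":
            return [(s, reg.uriref(HAS_PART), URIRef(a.object))]
        if a.kind == "quality":
            return [(s, reg.uriref(BEARER_OF), URIRef(a.object))]
        o = URIRef(a.object)
        return [(s, reg.uriref(BEARER_OF), o),
                (o, reg.uriref(HAS_VALUE), Literal(a.value)),
                (o, reg.uriref(HAS_UNIT), reg.uriref(a.unit))]

    def triples(self) -> set[tuple[URIRef, URIRef, object]]:
        out: set[tuple[URIRef, URIRef, object]] = set()
        for a in self.assertions:
            out.update(self.assertion_triples(a))
        return out

    def graph(self) -> Graph:
        g = Graph()
        for prefix, base in self.registry.prefix_map.items():
            g.bind(prefix, base)
        for t in self.triples():
            g.add(t)
        return g

    def serialize_turtle(self) -> str:
        """Canonical Turtle: prefix header plus sorted N-Triples-style body."""
        header = "".join(f"@prefix {p}: <{b}> .\n"
                         for p, b in sorted(self.registry.prefix_map.items()))
        lines = sorted(line + "\n"
                       for line in self.graph().serialize(format="nt").splitlines()
                       if line.strip())
        return header + "\n" + "".join(lines)

    def is_anatomical(self, uri: str) -> bool:
        node = self._require(uri)
        return any(self.registry.is_a(c, ANATOMICAL_ENTITY)
                   for c in node.asserted_classes if c in self.registry)


def create_description(registry: TermRegistry, root_class: str, label: str | None = None,
                       minting: MintingPolicy | None = None) -> PhenotypeKnowledgeGraph:
    """Start a description: a single ODU instance of ``root_class``.

    The ODU carries an instantiation assertion and (unless ``label`` is
    explicitly suppressed by passing ``""``) a human-readable label.
    """
    registry.resolve(root_class)
    minting = minting or MintingPolicy()
    if label is None:
        label = registry.label_of(root_class)
    odu_uri = minting.mint("odu")
    pkg = PhenotypeKnowledgeGraph(registry, odu_uri, minting)
    pkg.instances[odu_uri] = InstanceNode(uri=odu_uri, asserted_classes=[root_class],
                                          label=label or None)
    pkg.assertions.append(Assertion("instantiation", odu_uri, cls=root_class,
                                    category=CAT_INSTANTIATION))
    if label:
        pkg.assertions.append(Assertion("labeling", odu_uri, text=label,
                                        category=CAT_INSTANTIATION))
    return pkg
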