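"""Well-formedness checks, the content standard, DL compliance, querying.

Four layers of quality control over instance-based descriptions:

* :func:`check_wellformed` — structural invariants of a PKG (every instance
  has a class and a proper URI, the partonomy is a single-parent tree,
  measurements carry units, anatomical instances carry labels);
* :func:`check_shape` — the *content standard*: each named-graph category
  has a shape template (a semantic graph pattern) stating which roles a
  statement of that kind must bind; templates are loadable data
  (:func:`load_catalog`), with a default catalog shipped in
  ``data/shape_catalog.yaml`` and an RDF export for interoperability;
* :func:`dl_compliance` — detects the non-DL constructs (*has not part
  any*, *towards class*) that make an instance-level statement opaque to
  description-logics tooling;
* :func:`query_criteria` — criteria-based retrieval over a store: plain
  ABox pattern matching (no entailment regime), with optional subclass
  closure for class criteria and unit-checked measurement comparison
  (deliberately no unit conversion: mismatched units never match).
"""

from __future__ import annotations

import importlib.resources
import operator
from dataclasses import dataclass, field
from decimal import Decimal

import yaml
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS, SH

from .errors import DomainError, UnknownReferenceError
from .pkg import PhenotypeKnowledgeGraph
from .store import DescriptiveNamedGraph, Store
from .vocab import (ANATOMICAL_ENTITY, CAT_INSTANTIATION, CAT_PARTHOOD, EX_BASE,
                    HAS_PART, HAS_UNIT, HAS_VALUE, TermRegistry, BEARER_OF)


@dataclass(frozen=True)
class Finding:
    severity: str  # 'error' | 'warning'
    subject: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def error(self, subject: str, message: str) -> None:
        self.findings.append(Finding("error", subject, message))

    def warning(self, subject: str, message: str) -> None:
        self.findings.append(Finding("warning", subject, message))

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]


# ---------------------------------------------------------------------------
# well-formedness


def check_wellformed(pkg: PhenotypeKnowledgeGraph) -> ValidationReport:
    """Report structural violations; never raises."""
    report = ValidationReport()
    reg = pkg.registry
    for uri, node in pkg.instances.items():
        if not node.asserted_classes:
            report.error(uri, "instance carries no class assertion")
        if not uri.startswith(("http://", "https://", "urn:")):
            report.error(uri, "instance URI is blank or relative")
        if pkg.is_anatomical(uri) and node.label is None:
            report.warning(uri, "anatomical-entity instance has no label")
    parent: dict[str, str] = {}
    for a in pkg.assertions:
        if a.kind != "parthood":
            continue
        if a.object in parent:
            report.error(a.object, "part has more than one whole")
        parent[a.object] = a.subject
        if a.subject not in pkg.instances or a.object not in pkg.instances:
            report.error(a.subject, "parthood assertion references unknown instance")
    # cycle walk over the parent map
    for start in parent:
        seen = {start}
        cur = start
        while cur in parent:
            cur = parent[cur]
            if cur in seen:
                report.error(start, "parthood cycle detected")
                break
            seen.add(cur)
    for a in pkg.assertions:
        if a.kind == "measurement":
            if a.unit is None or not reg.is_unit(a.unit):
                report.error(a.subject, "measurement without a valid unit")
            if a.value is None:
                report.error(a.subject, "measurement without a value")
    return report


# ---------------------------------------------------------------------------
# shape templates (the content standard)


@dataclass(frozen=True)
class ShapeTemplate:
    category: str
    required_roles: tuple[str, ...]
    value_constraints: dict = field(default_factory=dict, hash=False)

    def __post_init__(self):
        if not self.required_roles:
            raise DomainError(f"template {self.category} declares no roles")


def load_catalog(path=None) -> dict[str, ShapeTemplate]:
    """Load a template catalog from YAML; default: the shipped catalog."""
    if path is None:
        text = (importlib.resources.files("phenokg") / "data" /
                "shape_catalog.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    catalog = {}
    for entry in raw["templates"]:
        t = ShapeTemplate(category=entry["category"],
                          required_roles=tuple(entry["roles"]),
                          value_constraints=dict(entry.get("constraints", {})))
        catalog[t.category] = t
    return catalog


def _bind_roles(graph: DescriptiveNamedGraph, registry: TermRegistry) -> dict:
    """Extract role bindings from a named graph's triples by pattern scan."""
    has_part = registry.uriref(HAS_PART)
    bearer_of = registry.uriref(BEARER_OF)
    has_value = registry.uriref(HAS_VALUE)
    has_unit = registry.uriref(HAS_UNIT)
    roles: dict[str, object] = {}
    borne = None
    for s, p, o in graph.triples:
        if p == has_part:
            roles["whole"], roles["part"] = s, o
        elif p == bearer_of:
            roles["bearer"], borne = s, o
        elif p == has_value:
            roles["value"] = o
        elif p == has_unit:
            roles["unit"] = o
        elif p == RDF.type and s == URIRef(graph.subject_part):
            roles.setdefault("instance", s)
            roles.setdefault("class", o)
    if borne is not None:
        for s, p, o in graph.triples:
            if s == borne and p == RDF.type:
                roles["quality"] = o
    return roles


def check_shape(graph: DescriptiveNamedGraph,
                catalog: dict[str, ShapeTemplate],
                registry: TermRegistry) -> ValidationReport:
    """Validate one named graph against the content standard."""
    report = ValidationReport()
    template = catalog.get(graph.category)
    if template is None:
        report.warning(graph.uri,
                       f"no template covers category {graph.category}")
        return report
    roles = _bind_roles(graph, registry)
    for role in template.required_roles:
        if role not in roles:
            report.error(graph.uri, f"required role {role!r} is not bound")
            continue
        constraint = template.value_constraints.get(role)
        if not constraint:
            continue
        value = roles[role]
        if "datatype" in constraint and constraint["datatype"] == "decimal":
            if not isinstance(value, Literal):
                report.error(graph.uri, f"role {role!r} must be a literal")
            else:
                try:
                    Decimal(str(value))
                except ArithmeticError:
                    report.error(graph.uri, f"role {role!r} is not decimal")
        if "under" in constraint:
            try:
                curie = registry.curie_for(str(value))
            except Exception:
                report.error(graph.uri, f"role {role!r} value {value} is not "
                                        "a registry term")
                continue
            if curie not in registry.subclass_closure(constraint["under"]):
                report.error(graph.uri,
                             f"role {role!r} value {curie} is not under "
                             f"{constraint['under']}")
    return report


def catalog_to_shacl(catalog: dict[str, ShapeTemplate],
                     registry: TermRegistry) -> str:
    """Export the catalog as SHACL node shapes (export-only interop aid;
    validation always runs on the internal engine)."""
    from rdflib import BNode, Graph

    g = Graph()
    g.bind("sh", SH)
    for template in catalog.values():
        shape = URIRef(f"{EX_BASE}shape/{template.category.split(':')[-1]}")
        g.add((shape, RDF.type, SH.NodeShape))
        g.add((shape, SH.targetClass, registry.uriref(template.category)))
        for role in template.required_roles:
            prop = BNode()
            g.add((shape, SH.property, prop))
            g.add((prop, SH.name, Literal(role)))
            g.add((prop, SH.minCount, Literal(1)))
    return g.serialize(format="turtle")


# ---------------------------------------------------------------------------
# DL compliance


def dl_compliance(statements, registry: TermRegistry) -> tuple[bool, list[str]]:
    """Scan statements for constructs outside description logics.

    Accepts an iterable of triples/quads, a pattern object with a
    ``dl_compliant``/``triples`` pair (the absence/exact-count builders'
    outputs), or a class expression (our expression subset is DL-safe by
    construction).  Returns (compliant, offending construct labels).
    """
    from .convert import AboxOnlyPattern, HybridPattern
    from .manchester import ClassExpression

    if isinstance(statements, ClassExpression):
        return True, []
    if isinstance(statements, HybridPattern):
        return True, []
    if isinstance(statements, AboxOnlyPattern):
        statements = statements.triples

    non_dl_uris = {URIRef(t.uri): t.label for t in registry.terms.values()
                   if t.non_dl}
    offending: list[str] = []
    for stmt in statements:
        p = stmt[1]
        if p in non_dl_uris and non_dl_uris[p] not in offending:
            offending.append(non_dl_uris[p])
    return not offending, offending


# ---------------------------------------------------------------------------
# criteria-based querying


@dataclass(frozen=True)
class QueryCriteria:
    """Conjunctive retrieval criteria over a store of descriptions.

    ``part_classes``: (class curie, use_closure) pairs the description must
    instantiate somewhere; ``parthood_pairs``: (whole class, part class)
    related by a parthood statement; ``measurements``: (kind class,
    comparator, value, unit) with comparator ∈ {>, >=, <, <=, =};
    ``taxon_class``: a class assertion required on the ODU.
    """

    part_classes: tuple[tuple[str, bool], ...] = ()
    parthood_pairs: tuple[tuple[str, str], ...] = ()
    measurements: tuple[tuple[str, str, Decimal, str], ...] = ()
    taxon_class: str | None = None

    def __post_init__(self):
        if not (self.part_classes or self.parthood_pairs or self.measurements
                or self.taxon_class):
            raise DomainError("query requires at least one criterion")


_COMPARATORS = {">": operator.gt, ">=": operator.ge, "<": operator.lt,
                "<=": operator.le, "=": operator.eq}


def _description_index(store: Store, description: str, registry: TermRegistry):
    """Collect instance classes, parthood edges and measurements from the
    active graphs of one description."""
    has_part = registry.uriref(HAS_PART)
    bearer_of = registry.uriref(BEARER_OF)
    has_value = registry.uriref(HAS_VALUE)
    has_unit = registry.uriref(HAS_UNIT)
    classes: dict[str, set[str]] = {}
    edges: list[tuple[str, str]] = []
    values: dict[str, Decimal] = {}
    units: dict[str, str] = {}
    bearers: list[str] = []
    for g in store.active_graphs(description):
        for s, p, o in g.triples:
            if p == RDF.type:
                try:
                    classes.setdefault(str(s), set()).add(registry.curie_for(str(o)))
                except Exception:
                    classes.setdefault(str(s), set())
            elif p == has_part:
                edges.append((str(s), str(o)))
            elif p == bearer_of:
                bearers.append(str(o))
            elif p == has_value:
                values[str(s)] = Decimal(str(o))
            elif p == has_unit:
                units[str(s)] = registry.curie_for(str(o))
    return classes, edges, values, units


def query_criteria(store: Store, criteria: QueryCriteria,
                   registry: TermRegistry) -> set[str]:
    """Return the description URIs whose active graphs satisfy all criteria."""
    for _, _, _, unit in criteria.measurements:
        if not registry.is_unit(unit):
            raise DomainError(f"{unit} is not a unit term")

    results: set[str] = set()
    for description in store.descriptions:
        classes, edges, values, units = _description_index(store, description,
                                                           registry)

        def instances_under(cls: str, closure: bool) -> set[str]:
            wanted = registry.subclass_closure(cls) if closure else {cls}
            return {uri for uri, cs in classes.items() if cs & wanted}

        ok = True
        for cls, closure in criteria.part_classes:
            if not instances_under(cls, closure):
                ok = False
        for whole_cls, part_cls in criteria.parthood_pairs:
            wholes = instances_under(whole_cls, True)
            parts = instances_under(part_cls, True)
            if not any(s in wholes and o in parts for s, o in edges):
                ok = False
        for kind, comp, value, unit in criteria.measurements:
            kinds = registry.subclass_closure(kind)
            hit = False
            for uri, v in values.items():
                if units.get(uri) != unit:
                    continue  # no unit conversion: mismatched units never match
                if classes.get(uri, set()) & kinds and \
                        _COMPARATORS[comp](v, Decimal(str(value))):
                    hit = True
            if not hit:
                ok = False
        if criteria.taxon_class is not None:
            odu = _odu_of(store, description)
            if odu is None or criteria.taxon_class not in classes.get(odu, set()):
                ok = False
        if ok:
            results.add(description)
    return results


def _odu_of(store: Store, description: str) -> str | None:
    for g in store.active_graphs(description):
        if g.category == CAT_INSTANTIATION:
            return g.subject_part
    return None
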