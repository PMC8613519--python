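"""Conversion between class-based (TBox) and instance-based (ABox) form.

``expand_to_abox`` performs skolemized existential instantiation: every
``some`` restriction over a parthood-style property mints exactly one
witness instance with its own URI, every ``exactly n`` restriction mints
``n`` witnesses *and* records a hybrid exact-count pattern (the cardinality
closure would otherwise be lost under the open-world assumption), and
``not`` mints nothing but records a hybrid absence pattern.  Expansion is
total: any subexpression that cannot be instantiated lands in the residue
with a reason, never an exception.

``rollup_to_tbox`` is the inverse: it folds an instance graph back into a
single class expression.  Measurements are deliberately *not* rolled up —
compiling numeric data into class axioms would need one phenotype class per
combination of values, which is exactly the failure mode of the class-based
representation — they are reported in a skip list instead.  Under
``closed_world`` the existential restrictions of a sibling group with an
identical rolled-up subtree are replaced by one qualified exact-cardinality
restriction, so re-expansion reproduces the original instance counts.

``build_absence`` / ``build_exact_count`` construct the two alternative
models for negative and quantitative observations: an ABox-only variant
using the non-DL properties *has not part any* / *towards class* (flagged
non-compliant), and a hybrid variant asserting a minted phenotype class
whose axiom is DL-compliant (``not (has part some X)`` /
``has component exactly n X``).

``comparative_to_direct`` grounds a comparative statement ("increased
length of abdomen") into a direct bounded statement ("length above
2.6 mm") — possible only when the reference value is known.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from decimal import Decimal

from rdflib import BNode, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import DomainError, UnknownReferenceError, UnresolvableComparativeError
from .manchester import (ClassExpression, and_, atomic, exactly, not_, serialize_manchester,
                         some)
from .pkg import MintingPolicy, PhenotypeKnowledgeGraph, create_description
from .vocab import (BEARER_OF, CAT_PARTHOOD, EX_BASE, HAS_COMPONENT, HAS_NOT_PART_ANY,
                    HAS_PART, HAS_VALUE, TOWARDS_CLASS, TermRegistry)

PART_PROPERTIES = (HAS_PART, HAS_COMPONENT)


@dataclass(frozen=True)
class HybridPattern:
    """A DL-compliant class-expression pattern asserted on an instance.

    The phenotype class URI is minted deterministically from the
    expression's canonical serialization, so identical patterns unify
    across descriptions.
    """

    kind: str  # 'absence' | 'exact-count'
    bearer: str
    expression: ClassExpression
    class_uri: str
    dl_compliant: bool = True

    def class_assertion_triple(self):
        return (URIRef(self.bearer), RDF.type, URIRef(self.class_uri))

    def to_triples(self, registry: TermRegistry) -> list:
        """OWL triple encoding: the bearer's class assertion plus the minted
        class's equivalent-class axiom (anonymous classes as blank nodes —
        legal in the TBox; the instance level stays blank-node free)."""
        triples = [self.class_assertion_triple()]
        cls = URIRef(self.class_uri)
        triples.append((cls, RDF.type, OWL.Class))
        triples.append((cls, RDFS.label, Literal(self.kind + " phenotype")))
        node, extra = _encode_expression(self.expression, registry)
        triples.append((cls, OWL.equivalentClass, node))
        triples.extend(extra)
        return triples


def _encode_expression(expr: ClassExpression, registry: TermRegistry):
    """Encode a class expression as OWL triples; returns (node, triples)."""
    if expr.kind == "atomic":
        return registry.uriref(expr.term), []
    node = BNode()
    triples: list = [(node, RDF.type, OWL.Class)]
    if expr.kind == "not":
        inner, extra = _encode_expression(expr.operands[0], registry)
        triples.append((node, OWL.complementOf, inner))
        triples.extend(extra)
        return node, triples
    if expr.kind == "and":
        members = []
        for op in expr.operands:
            inner, extra = _encode_expression(op, registry)
            members.append(inner)
            triples.extend(extra)
        head = BNode()
        triples.append((node, OWL.intersectionOf, head))
        for i, member in enumerate(members):
            triples.append((head, RDF.first, member))
            nxt = BNode() if i < len(members) - 1 else RDF.nil
            triples.append((head, RDF.rest, nxt))
            head = nxt
        return node, triples
    triples = [(node, RDF.type, OWL.Restriction),
               (node, OWL.onProperty, registry.uriref(expr.property))]
    inner, extra = _encode_expression(expr.filler, registry)
    triples.extend(extra)
    if expr.kind == "some":
        triples.append((node, OWL.someValuesFrom, inner))
    else:
        triples.append((node, OWL.qualifiedCardinality,
                        Literal(expr.cardinality, datatype=XSD.nonNegativeInteger)))
        triples.append((node, OWL.onClass, inner))
    return node, triples


def mint_pattern_class_uri(expr: ClassExpression, registry: TermRegistry) -> str:
    digest = hashlib.sha256(
        serialize_manchester(expr, registry).encode()).hexdigest()[:16]
    return f"{EX_BASE}pattern/{digest}"


# ---------------------------------------------------------------------------
# expansion


@dataclass
class ExpansionResult:
    pkg: PhenotypeKnowledgeGraph
    residue: list[tuple[str, ClassExpression, str]] = field(default_factory=list)
    hybrid_assertions: list[HybridPattern] = field(default_factory=list)

    def instances_of(self, cls: str) -> list[str]:
        return [uri for uri, node in self.pkg.instances.items()
                if cls in node.asserted_classes]


def _atomic_head(filler: ClassExpression) -> tuple[str | None, list[ClassExpression]]:
    """Split a filler into its first atomic class and the remaining conjuncts."""
    head = None
    rest = []
    for c in filler.conjuncts():
        if c.kind == "atomic" and head is None:
            head = c.term
        else:
            rest.append(c)
    return head, rest


def expand_to_abox(expr: ClassExpression, registry: TermRegistry, odu_class: str,
                   minting: MintingPolicy | None = None) -> ExpansionResult:
    """Skolemize a class expression into an instance-based description.

    The ODU is created as an instance of ``odu_class``; the expression's
    atomic conjuncts become further class assertions on it.  Total: never
    raises on expression shape; unexpandable subexpressions go to residue.
    """
    pkg = create_description(registry, odu_class, minting=minting or MintingPolicy())
    result = ExpansionResult(pkg=pkg)

    def mint_witness(bearer: str, prop: str, filler: ClassExpression) -> None:
        head, rest = _atomic_head(filler)
        if head is None:
            result.residue.append((bearer, filler,
                                   "filler has no atomic class to instantiate"))
            return
        if prop in PART_PROPERTIES:
            uri = pkg.add_part(bearer, head)
        else:  # bearer of — a quality witness
            category = registry.category_for_quality(head)
            if category is None:
                result.residue.append(
                    (bearer, filler,
                     f"no perceptual category known for quality {head}"))
                return
            uri = pkg.add_quality(bearer, head, category)
        for sub in rest:
            expand_onto(uri, sub)

    def expand_onto(bearer: str, node: ClassExpression) -> None:
        for c in node.conjuncts():
            if c.kind == "atomic":
                pkg.assert_class(bearer, c.term)
            elif c.kind == "not":
                cls_uri = mint_pattern_class_uri(c, registry)
                result.hybrid_assertions.append(
                    HybridPattern("absence", bearer, c, cls_uri))
            elif c.kind == "some":
                if c.property in PART_PROPERTIES or c.property == BEARER_OF:
                    mint_witness(bearer, c.property, c.filler)
                else:
                    result.residue.append(
                        (bearer, c, f"property {c.property} is not instantiated "
                                    "as parts or qualities"))
            elif c.kind == "exactly":
                if c.property in PART_PROPERTIES:
                    for _ in range(c.cardinality):
                        mint_witness(bearer, c.property, c.filler)
                    cls_uri = mint_pattern_class_uri(c, registry)
                    result.hybrid_assertions.append(
                        HybridPattern("exact-count", bearer, c, cls_uri))
                else:
                    result.residue.append(
                        (bearer, c, f"exact cardinality on {c.property} is not "
                                    "instantiated"))

    expand_onto(pkg.odu_uri, expr)
    return result


def expected_witness_counts(expr: ClassExpression) -> dict[str, int]:
    """Closed-form witness count per class implied by an expression: 1 per
    ``some``, n per ``exactly``, multiplied down nested fillers; ``not``
    subtrees mint nothing.  Used as the expansion contract."""
    counts: dict[str, int] = {}

    def visit(node: ClassExpression, multiplier: int) -> None:
        if node.kind == "not":
            return
        if node.kind == "and":
            for op in node.operands:
                visit(op, multiplier)
            return
        if node.kind in ("some", "exactly"):
            m = multiplier * (1 if node.kind == "some" else node.cardinality)
            head, rest = _atomic_head(node.filler)
            if head is not None:
                counts[head] = counts.get(head, 0) + m
                for sub in rest:
                    visit(sub, m)

    visit(expr, 1)
    return counts


# ---------------------------------------------------------------------------
# roll-up


@dataclass
class RollupResult:
    expression: ClassExpression
    skipped_measurements: list = field(default_factory=list)


def rollup_to_tbox(pkg: PhenotypeKnowledgeGraph, root: str,
                   closed_world: bool = False) -> RollupResult:
    """Fold an instance graph into the implicit class expression it shortens.

    Recursively conjoins the root's asserted classes with one restriction
    per child part (``has part some <subtree>``) and per quality
    (``bearer of some <class>``).  ``closed_world`` groups same-subtree
    sibling parts into ``has part exactly n <subtree>``.  Measurements are
    skipped and reported.
    """
    if root not in pkg.instances:
        raise UnknownReferenceError(f"unknown instance URI {root!r}")

    children: dict[str, list[str]] = {}
    qualities: dict[str, list[str]] = {}
    skipped: list = []
    for a in pkg.assertions:
        if a.kind == "parthood":
            children.setdefault(a.subject, []).append(a.object)
        elif a.kind == "quality":
            qualities.setdefault(a.subject, []).append(a.object)
        elif a.kind == "measurement":
            skipped.append(a)

    def roll(uri: str) -> ClassExpression:
        conjuncts = [atomic(c) for c in pkg.instances[uri].asserted_classes]
        for q_uri in qualities.get(uri, ()):
            q_expr = and_(*(atomic(c)
                            for c in pkg.instances[q_uri].asserted_classes))
            conjuncts.append(some(BEARER_OF, q_expr))
        child_exprs = [roll(c) for c in children.get(uri, ())]
        if closed_world:
            groups: dict[tuple, tuple[ClassExpression, int]] = {}
            for e in child_exprs:
                key = e.sort_key()
                prev = groups.get(key)
                groups[key] = (e, (prev[1] if prev else 0) + 1)
            for e, n in groups.values():
                conjuncts.append(exactly(HAS_PART, n, e))
        else:
            conjuncts.extend(some(HAS_PART, e) for e in child_exprs)
        return and_(*conjuncts)

    return RollupResult(expression=roll(root), skipped_measurements=skipped)


# ---------------------------------------------------------------------------
# absence and exact-count variants


@dataclass(frozen=True)
class AboxOnlyPattern:
    """Instance-level encoding of a negative/quantitative observation using
    a non-DL property; flagged non-compliant."""

    kind: str
    bearer: str
    triples: tuple
    dl_compliant: bool = False


def build_absence(variant: str, registry: TermRegistry, bearer: str,
                  absent_class: str):
    """Model "bearer lacks any <absent_class> part" in one of two ways.

    ``abox-only``: one triple with the *has not part any* property (outside
    OWL syntax → not DL-compliant).  ``hybrid``: a minted phenotype class
    defined as ``not (has part some <absent_class>)`` asserted on the
    bearer (DL-compliant, machine-actionable).
    """
    registry.resolve(absent_class)
    if variant == "abox-only":
        t = (URIRef(bearer), registry.uriref(HAS_NOT_PART_ANY),
             registry.uriref(absent_class))
        return AboxOnlyPattern("absence", bearer, (t,))
    if variant == "hybrid":
        expr = not_(some(HAS_PART, atomic(absent_class)))
        return HybridPattern("absence", bearer, expr,
                             mint_pattern_class_uri(expr, registry))
    raise DomainError(f"unknown absence variant {variant!r}")


def build_exact_count(variant: str, registry: TermRegistry, bearer: str,
                      part_class: str, n: int):
    """Model "bearer has exactly n parts of <part_class>" in one of two ways.

    ``abox-only``: a minted count-quality instance linked to the bearer,
    carrying the integer value and a *towards class* link to the part class
    (not DL-compliant).  ``hybrid``: a minted phenotype class defined as
    ``has component exactly n <part_class>`` asserted on the bearer.
    """
    registry.resolve(part_class)
    if n < 0:
        raise DomainError("exact count must be non-negative")
    if variant == "abox-only":
        count_uri = URIRef(f"{bearer}/count-{part_class.split(':')[-1]}")
        b = URIRef(bearer)
        triples = (
            (b, registry.uriref(BEARER_OF), count_uri),
            (count_uri, RDF.type, registry.uriref("EX:count-quality")),
            (count_uri, registry.uriref(TOWARDS_CLASS), registry.uriref(part_class)),
            (count_uri, registry.uriref(HAS_VALUE),
             Literal(n, datatype=XSD.nonNegativeInteger)),
        )
        return AboxOnlyPattern("exact-count", bearer, triples)
    if variant == "hybrid":
        expr = exactly(HAS_COMPONENT, n, atomic(part_class))
        return HybridPattern("exact-count", bearer, expr,
                             mint_pattern_class_uri(expr, registry))
    raise DomainError(f"unknown exact-count variant {variant!r}")


# ---------------------------------------------------------------------------
# comparative statements


@dataclass(frozen=True)
class ComparativeStatement:
    """A quality described relative to a reference condition (e.g. a
    wild-type): direction of change plus, if known, the reference value."""

    quality_kind: str
    bearer_class: str
    direction: str  # 'increased' | 'decreased'
    reference_value: Decimal | None = None
    reference_unit: str | None = None

    def __post_init__(self):
        if self.direction not in ("increased", "decreased"):
            raise DomainError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class BoundedDirectStatement:
    """A direct, self-contained bound on a quality's magnitude."""

    quality_kind: str
    bearer_class: str
    bound_kind: str  # 'exclusive-lower' | 'exclusive-upper'
    bound_value: Decimal
    unit: str


def comparative_to_direct(stmt: ComparativeStatement) -> BoundedDirectStatement:
    """Ground a comparative statement against its reference value.

    "Increased" relative to a reference of v becomes an exclusive lower
    bound at v; "decreased" an exclusive upper bound.  Without the
    reference value the comparison carries no usable magnitude at all and
    the conversion fails.
    """
    if stmt.reference_value is None or stmt.reference_unit is None:
        raise UnresolvableComparativeError(
            "comparative statement has no reference value: the actual "
            "magnitude cannot be derived without consulting the reference "
            "description")
    bound = "exclusive-lower" if stmt.direction == "increased" else "exclusive-upper"
    return BoundedDirectStatement(quality_kind=stmt.quality_kind,
                                  bearer_class=stmt.bearer_class,
                                  bound_kind=bound,
                                  bound_value=Decimal(str(stmt.reference_value)),
                                  unit=stmt.reference_unit)
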