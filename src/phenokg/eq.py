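"""Entity–Quality (EQ) phenotype statements and their class-axiom form.

An EQ statement annotates a bearer *entity* (an anatomical entity class)
with a *quality* (a quality-ontology class).  The historical EAV form
(entity + attribute + value, e.g. eye + color + red) survives as an optional
``attribute``: because quality ontologies organize values under attribute
parents (red is-a color), the attribute is the quality's ancestor and is
usually implicit.  Two extensions cover statements the plain bipartite form
cannot express:

* ``related_entity`` (E(QRE)) — relational qualities, e.g. a length
  increased relative to the length of some other structure;
* ``count`` (E(QC)) — quantitative statements about how many parts of a
  kind the bearer has.

:func:`eq_to_expression` compiles a statement onto the standard
post-composition scheme

    has part some (E and (bearer of some Q))

with the related entity nested under the relating property (default
*increased in magnitude relative to*) and counts compiled onto a
``has component exactly C E`` qualified cardinality.  :func:`expression_to_eq`
inverts the scheme by structural pattern matching — no reasoning — and
rejects anything outside its image (negation, unrelated multi-quality
conjunctions, foreign properties) with :class:`NotEQRepresentableError`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, NotEQRepresentableError
from .manchester import ClassExpression, and_, atomic, exactly, some
from .vocab import BEARER_OF, HAS_COMPONENT, HAS_PART, INCREASED_RELATIVE_TO, TermRegistry

DEFAULT_RELATING_PROPERTY = INCREASED_RELATIVE_TO


@dataclass(frozen=True)
class EQStatement:
    """One phenotype annotation: E, optional Q / attribute / RE / C."""

    entity: str
    quality: str | None = None
    attribute: str | None = None
    related_entity: str | None = None
    count: int | None = None

    def __post_init__(self):
        if self.related_entity is not None and self.quality is None:
            raise DomainError("related_entity requires a quality")
        if self.related_entity is not None and self.count is not None:
            raise DomainError("count and related_entity are mutually exclusive")
        if self.count is not None and self.count < 0:
            raise DomainError("count must be non-negative")


def _quality_filler(eq: EQStatement, relating_property: str) -> ClassExpression:
    parts: list[ClassExpression] = [atomic(eq.quality)]
    if eq.attribute is not None:
        parts.append(atomic(eq.attribute))
    if eq.related_entity is not None:
        parts.append(some(relating_property, atomic(eq.related_entity)))
    return and_(*parts)


def eq_to_expression(eq: EQStatement, registry: TermRegistry,
                     relating_property: str = DEFAULT_RELATING_PROPERTY) -> ClassExpression:
    """Compile an EQ statement to its Manchester-subset class expression.

    The relating property used for E(QRE) statements is a parameter; the
    default is the magnitude-comparison property.  Never emits ``not``.
    """
    for curie in filter(None, (eq.entity, eq.quality, eq.attribute, eq.related_entity)):
        registry.resolve(curie)
    if eq.attribute is not None and eq.quality is not None and \
            not registry.is_a(eq.quality, eq.attribute):
        raise DomainError(
            f"attribute {eq.attribute} must subsume quality {eq.quality}")

    if eq.quality is not None:
        base = some(HAS_PART, and_(atomic(eq.entity),
                                   some(BEARER_OF, _quality_filler(eq, relating_property))))
    else:
        base = some(HAS_PART, atomic(eq.entity))

    if eq.count is None:
        return base
    count_expr = exactly(HAS_COMPONENT, eq.count, atomic(eq.entity))
    if eq.quality is None:
        return count_expr
    return and_(base, count_expr)


def _reject(node: ClassExpression, why: str) -> NotEQRepresentableError:
    return NotEQRepresentableError(
        f"not EQ-representable: {why}", offending=node)


def _invert_quality_filler(filler: ClassExpression, registry: TermRegistry | None):
    """Return (quality, attribute, related_entity, relating_property)."""
    atoms: list[str] = []
    related, rel_prop = None, None
    for c in filler.conjuncts():
        if c.kind == "atomic":
            atoms.append(c.term)
        elif c.kind == "some" and c.filler.kind == "atomic":
            if related is not None:
                raise _reject(c, "more than one related-entity restriction")
            related, rel_prop = c.filler.term, c.property
        else:
            raise _reject(c, f"unexpected {c.kind} node inside quality filler")
    if not atoms:
        raise _reject(filler, "quality filler has no atomic quality class")
    if len(atoms) == 1:
        return atoms[0], None, related, rel_prop
    if len(atoms) == 2:
        if registry is None:
            raise _reject(filler, "two quality conjuncts but no registry to "
                                  "decide which is the attribute")
        a, b = atoms
        if registry.is_a(a, b):
            return a, b, related, rel_prop
        if registry.is_a(b, a):
            return b, a, related, rel_prop
        raise _reject(filler, f"qualities {a} and {b} are hierarchically unrelated")
    raise _reject(filler, "nested multi-quality conjunction")


def _invert_plain(expr: ClassExpression, registry: TermRegistry | None) -> EQStatement:
    """Invert a single has-part existential restriction."""
    assert expr.kind == "some" and expr.property == HAS_PART
    filler = expr.filler
    if filler.kind == "atomic":
        return EQStatement(entity=filler.term)
    entity, bearer = None, None
    for c in filler.conjuncts():
        if c.kind == "atomic":
            if entity is not None:
                raise _reject(c, "more than one entity class under has part")
            entity = c.term
        elif c.kind == "some" and c.property == BEARER_OF:
            if bearer is not None:
                raise _reject(c, "more than one bearer-of restriction")
            bearer = c
        else:
            raise _reject(c, f"unexpected {c.kind} node under has part")
    if entity is None or bearer is None:
        raise _reject(filler, "has-part filler is not of the E-and-quality shape")
    quality, attribute, related, _ = _invert_quality_filler(bearer.filler, registry)
    return EQStatement(entity=entity, quality=quality, attribute=attribute,
                       related_entity=related)


def expression_to_eq(expr: ClassExpression,
                     registry: TermRegistry | None = None) -> EQStatement:
    """Invert :func:`eq_to_expression` on its image (structural match only)."""
    for node in expr.walk():
        if node.kind == "not":
            raise _reject(node, "negation lies outside the EQ subset")

    if expr.kind == "some" and expr.property == HAS_PART:
        return _invert_plain(expr, registry)
    if expr.kind == "exactly" and expr.property == HAS_COMPONENT \
            and expr.filler.kind == "atomic":
        return EQStatement(entity=expr.filler.term, count=expr.cardinality)
    if expr.kind == "and":
        count_nodes = [c for c in expr.operands
                       if c.kind == "exactly" and c.property == HAS_COMPONENT
                       and c.filler.kind == "atomic"]
        plain_nodes = [c for c in expr.operands
                       if c.kind == "some" and c.property == HAS_PART]
        if len(count_nodes) == 1 and len(plain_nodes) == 1 \
                and len(expr.operands) == 2:
            base = _invert_plain(plain_nodes[0], registry)
            count_node = count_nodes[0]
            if count_node.filler.term != base.entity:
                raise _reject(count_node,
                              "count restriction names a different entity")
            return EQStatement(entity=base.entity, quality=base.quality,
                               attribute=base.attribute, count=count_node.cardinality)
    raise _reject(expr, f"top-level {expr.kind} node outside the EQ image")
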