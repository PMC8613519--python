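"""OWL Manchester-syntax subset: expression trees, parser, serializer.

The class-based (TBox) representation of a phenotype carries the actual
descriptive content inside a class axiom.  This module implements the
algebra those axioms are written in — the Manchester-syntax subset of

* atomic class references (multi-word labels, matched against a registry),
* ``and`` (set intersection, flattened and canonically ordered),
* ``not`` (complement, exactly one operand),
* ``<property> some <filler>`` (existential restriction),
* ``<property> exactly <n> <filler>`` (qualified exact cardinality),

with parentheses.  ``min``/``max``/``only``/``value`` are deliberately
rejected: the subset mirrors what phenotype class axioms in the field
actually use.  Tokenization is registry-driven: class and property labels
(including multi-word ones such as "insect head" or "increased in magnitude
relative to") are matched longest-first, keywords take precedence.

Canonical form
--------------
``and`` nodes are flattened (left-associative parses collapse into one
n-ary node) and their operands sorted by a registry-free structural key, so
two expressions denoting the same intersection compare equal and
``parse(serialize(e)) == canonical(e)`` holds for every expression ``e`` of
the subset, and ``serialize(parse(t)) == t`` for every canonically
serialized text ``t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import ManchesterSyntaxError, UnknownTermError
from .vocab import TermRegistry

NODE_KINDS = ("atomic", "and", "not", "some", "exactly")

_UNSUPPORTED_KEYWORDS = ("min", "max", "only", "value", "or")


@dataclass(frozen=True)
class ClassExpression:
    """Immutable, well-kinded class-expression tree node.

    Use the constructors :func:`atomic`, :func:`and_`, :func:`not_`,
    :func:`some`, :func:`exactly` rather than instantiating directly; they
    enforce the per-kind shape constraints and canonicalize ``and`` nodes.
    """

    kind: str
    term: str | None = None
    operands: tuple["ClassExpression", ...] = ()
    property: str | None = None
    cardinality: int | None = None
    filler: "ClassExpression | None" = None

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        checks = {
            "atomic": self.term is not None and not self.operands and self.filler is None,
            "and": len(self.operands) >= 2 and self.term is None,
            "not": len(self.operands) == 1 and self.term is None,
            "some": self.property is not None and self.filler is not None,
            "exactly": (self.property is not None and self.filler is not None
                        and isinstance(self.cardinality, int) and self.cardinality >= 0),
        }
        if not checks[self.kind]:
            raise ValueError(f"ill-formed {self.kind} node")

    # structural, registry-free ordering key; used to canonicalize `and`
    def sort_key(self) -> tuple:
        return (self.kind, self.term or "", self.property or "",
                self.cardinality if self.cardinality is not None else -1,
                self.filler.sort_key() if self.filler else (),
                tuple(op.sort_key() for op in self.operands))

    def conjuncts(self) -> tuple["ClassExpression", ...]:
        """Operands if this is an ``and`` node, else the node itself."""
        return self.operands if self.kind == "and" else (self,)

    def walk(self):
        """Yield every node of the tree, pre-order."""
        yield self
        if self.filler is not None:
            yield from self.filler.walk()
        for op in self.operands:
            yield from op.walk()

    def curies(self) -> set[str]:
        out = set()
        for node in self.walk():
            if node.term:
                out.add(node.term)
            if node.property:
                out.add(node.property)
        return out

    def to_json_dict(self) -> dict:
        d: dict = {"node_kind": self.kind}
        if self.term is not None:
            d["term"] = self.term
        if self.property is not None:
            d["property"] = self.property
        if self.cardinality is not None:
            d["cardinality"] = self.cardinality
        if self.filler is not None:
            d["filler"] = self.filler.to_json_dict()
        if self.operands:
            d["operands"] = [op.to_json_dict() for op in self.operands]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)

    @classmethod
    def from_json_dict(cls, d: dict) -> "ClassExpression":
        kind = d["node_kind"]
        if kind == "atomic":
            return atomic(d["term"])
        if kind == "and":
            return and_(*(cls.from_json_dict(x) for x in d["operands"]))
        if kind == "not":
            return not_(cls.from_json_dict(d["operands"][0]))
        filler = cls.from_json_dict(d["filler"])
        if kind == "some":
            return some(d["property"], filler)
        return exactly(d["property"], d["cardinality"], filler)


def atomic(term: str) -> ClassExpression:
    return ClassExpression("atomic", term=term)


def and_(*operands: ClassExpression) -> ClassExpression:
    """Flattening, sorting intersection constructor.

    Nested ``and`` operands are spliced in; duplicates are kept (A ⊓ A is
    logically A, but collapsing them would silently change witness counts
    when the expression is later instantiated).  A single operand is
    returned unchanged.
    """
    flat: list[ClassExpression] = []
    for op in operands:
        flat.extend(op.conjuncts())
    if not flat:
        raise ValueError("and requires at least one operand")
    if len(flat) == 1:
        return flat[0]
    return ClassExpression("and", operands=tuple(sorted(flat, key=lambda e: e.sort_key())))


def not_(operand: ClassExpression) -> ClassExpression:
    return ClassExpression("not", operands=(operand,))


def some(prop: str, filler: ClassExpression) -> ClassExpression:
    return ClassExpression("some", property=prop, filler=filler)


def exactly(prop: str, n: int, filler: ClassExpression) -> ClassExpression:
    return ClassExpression("exactly", property=prop, cardinality=n, filler=filler)


# ---------------------------------------------------------------------------
# tokenizer


@dataclass(frozen=True)
class _Token:
    kind: str  # 'lparen' | 'rparen' | 'keyword' | 'int' | 'class' | 'property'
    value: str
    pos: int


def _boundary_ok(text: str, end: int) -> bool:
    return end >= len(text) or not (text[end].isalnum() or text[end] == "_")


def tokenize(text: str, registry: TermRegistry) -> list[_Token]:
    """Registry-driven tokenizer.

    At each position: parentheses, then keywords, then registry labels
    longest-first (so "color brightness" beats "color", and digit-bearing
    labels such as "flagellomere 14" tokenize as one atom), then integers.
    Anything else is an unknown-term error naming the offending token.
    """
    labels = registry.labels()
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append(_Token("lparen" if c == "(" else "rparen", c, i))
            i += 1
            continue
        matched = False
        for kw in ("exactly", "and", "not", "some", *_UNSUPPORTED_KEYWORDS):
            if text.startswith(kw, i) and _boundary_ok(text, i + len(kw)):
                if kw in _UNSUPPORTED_KEYWORDS:
                    raise ManchesterSyntaxError(
                        f"unsupported Manchester keyword {kw!r}", i)
                tokens.append(_Token("keyword", kw, i))
                i += len(kw)
                matched = True
                break
        if matched:
            continue
        for lab in labels:
            if text.startswith(lab, i) and _boundary_ok(text, i + len(lab)):
                term = registry.by_label(lab)
                kind = "property" if term.term_kind == "object-property" else "class"
                tokens.append(_Token(kind, term.curie, i))
                i += len(lab)
                matched = True
                break
        if matched:
            continue
        if c.isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            tokens.append(_Token("int", text[i:j], i))
            i = j
            continue
        frag = text[i:].split()[0] if text[i:].split() else text[i:]
        raise UnknownTermError(
            frag, f"token {frag!r} at position {i} is neither a keyword nor a "
                  f"registered class or property label")
    return tokens


# ---------------------------------------------------------------------------
# parser (recursive descent)
#
#   expression := conjunct ( 'and' conjunct )*
#   conjunct   := 'not' primary | PROPERTY 'some' primary
#               | PROPERTY 'exactly' INT primary | primary
#   primary    := '(' expression ')' | CLASS


class _Parser:
    def __init__(self, tokens: list[_Token], length: int):
        self.tokens = tokens
        self.i = 0
        self.length = length

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise ManchesterSyntaxError("unexpected end of expression", self.length)
        self.i += 1
        return tok

    def expression(self) -> ClassExpression:
        ops = [self.conjunct()]
        while (tok := self.peek()) is not None and tok.kind == "keyword" and tok.value == "and":
            self.take()
            ops.append(self.conjunct())
        return and_(*ops)

    def conjunct(self) -> ClassExpression:
        tok = self.peek()
        if tok is None:
            raise ManchesterSyntaxError("unexpected end of expression", self.length)
        if tok.kind == "keyword" and tok.value == "not":
            self.take()
            return not_(self.primary())
        if tok.kind == "property":
            prop = self.take()
            kw = self.take()
            if kw.kind != "keyword" or kw.value not in ("some", "exactly"):
                raise ManchesterSyntaxError(
                    f"property {prop.value!r} must be followed by 'some' or 'exactly'",
                    kw.pos)
            if kw.value == "some":
                return some(prop.value, self.primary())
            num = self.take()
            if num.kind != "int":
                raise ManchesterSyntaxError("'exactly' requires an integer", num.pos)
            return exactly(prop.value, int(num.value), self.primary())
        return self.primary()

    def primary(self) -> ClassExpression:
        tok = self.take()
        if tok.kind == "lparen":
            inner = self.expression()
            closing = self.peek()
            if closing is None or closing.kind != "rparen":
                raise ManchesterSyntaxError("unbalanced parentheses: missing ')'", tok.pos)
            self.take()
            return inner
        if tok.kind == "class":
            return atomic(tok.value)
        if tok.kind == "rparen":
            raise ManchesterSyntaxError("unbalanced parentheses: unexpected ')'", tok.pos)
        raise ManchesterSyntaxError(f"unexpected token {tok.value!r}", tok.pos)


def parse_manchester(text: str, registry: TermRegistry) -> ClassExpression:
    """Parse Manchester-subset text into a canonical :class:`ClassExpression`."""
    if not text or not text.strip():
        raise ManchesterSyntaxError("empty expression", 0)
    parser = _Parser(tokenize(text, registry), len(text))
    expr = parser.expression()
    trailing = parser.peek()
    if trailing is not None:
        if trailing.kind == "rparen":
            raise ManchesterSyntaxError("unbalanced parentheses: unexpected ')'",
                                        trailing.pos)
        raise ManchesterSyntaxError(f"unexpected trailing token {trailing.value!r}",
                                    trailing.pos)
    return expr


# ---------------------------------------------------------------------------
# serializer


def serialize_manchester(expr: ClassExpression, registry: TermRegistry) -> str:
    """Canonical text: single spaces, parentheses around every non-atomic operand."""

    def wrap(e: ClassExpression) -> str:
        s = ser(e)
        return s if e.kind == "atomic" else f"( {s} )"

    def ser(e: ClassExpression) -> str:
        if e.kind == "atomic":
            return registry.label_of(e.term)
        if e.kind == "and":
            return " and ".join(wrap(op) for op in e.operands)
        if e.kind == "not":
            return f"not {wrap(e.operands[0])}"
        label = registry.label_of(e.property)
        if e.kind == "some":
            return f"{label} some {wrap(e.filler)}"
        return f"{label} exactly {e.cardinality} {wrap(e.filler)}"

    return ser(expr)


def validate_expression(expr: ClassExpression, registry: TermRegistry) -> None:
    """Check every CURIE in the tree resolves; raises UnknownTermError."""
    for curie in sorted(expr.curies()):
        registry.resolve(curie)
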