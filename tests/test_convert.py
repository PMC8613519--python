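"""TBox↔ABox conversion, absence/count variants, comparative grounding."""

import random
from decimal import Decimal

import pytest

from phenokg.convert import (AboxOnlyPattern, ComparativeStatement, HybridPattern,
                             build_absence, build_exact_count, comparative_to_direct,
                             expand_to_abox, rollup_to_tbox)
from phenokg.eq import EQStatement, expression_to_eq
from phenokg.errors import (DomainError, UnknownReferenceError,
                            UnresolvableComparativeError)
from phenokg.manchester import (atomic, not_, parse_manchester, serialize_manchester,
                                some)
from phenokg.pkg import create_description
from phenokg.synth import (GeneratorParams, WORKED_HEAD_AXIOM, build_organism_pkg,
                           generate_pkg)
from phenokg.validate import dl_compliance
from phenokg.vocab import CAT_COLOR, HAS_PART

from .conftest import partonomy_signature, random_expression


def test_worked_head_axiom_expands_to_captioned_counts(registry):
    """One insect head (the ODU), one flattened quality, two antenna
    witnesses, plus one hybrid exact-count entry for the antennae."""
    tree = parse_manchester(WORKED_HEAD_AXIOM, registry)
    result = expand_to_abox(tree, registry, "UBERON:6000004")
    assert len(result.instances_of("UBERON:6000004")) == 1
    assert len(result.instances_of("PATO:0002254")) == 1
    assert len(result.instances_of("UBERON:0000972")) == 2
    assert [h.kind for h in result.hybrid_assertions] == ["exact-count"]
    assert result.residue == []


def test_atomic_expression_expands_to_single_instance(registry):
    result = expand_to_abox(atomic("UBERON:6000004"), registry, "UBERON:6000004")
    assert len(result.pkg.instances) == 1
    assert result.residue == [] and result.hybrid_assertions == []


def test_absence_expands_to_hybrid_entry_without_minting(registry):
    expr = parse_manchester("abdomen and not ( has part some ovipositor )", registry)
    result = expand_to_abox(expr, registry, "EX:abdomen")
    assert len(result.pkg.instances) == 1  # nothing minted for the negation
    assert [h.kind for h in result.hybrid_assertions] == ["absence"]
    assert result.hybrid_assertions[0].bearer == result.pkg.odu_uri


def test_expansion_is_total_with_residue(registry):
    expr = parse_manchester(
        "antenna and ( bearer of some ( length and increased in magnitude "
        "relative to some ( length and inheres in some eye ) ) )", registry)
    result = expand_to_abox(expr, registry, "UBERON:0000972")
    # the foreign-property restriction lands in residue, never an exception
    assert result.residue
    assert all(reason for _, _, reason in result.residue)


def test_witness_counts_match_ast_interpreter_oracle(registry):
    """Per-class minted witness counts equal an independent recursive
    interpretation of the expression: 1 per `some`, n per `exactly`,
    multiplied down nested fillers; `not` subtrees mint nothing."""

    def oracle(expr, multiplier, out):
        if expr.kind == "not":
            return
        if expr.kind == "and":
            for op in expr.operands:
                oracle(op, multiplier, out)
        elif expr.kind in ("some", "exactly"):
            m = multiplier * (1 if expr.kind == "some" else expr.cardinality)
            head, rest = None, []
            for c in expr.filler.conjuncts():
                if c.kind == "atomic" and head is None:
                    head = c.term
                else:
                    rest.append(c)
            if head is not None:
                out[head] = out.get(head, 0) + m
                for r in rest:
                    oracle(r, m, out)

    rng = random.Random(0)
    for _ in range(100):
        expr = random_expression(rng, 3)
        result = expand_to_abox(expr, registry, "EX:multicellular-organism")
        minted = {}
        for uri, node in result.pkg.instances.items():
            if uri == result.pkg.odu_uri:
                continue
            first = node.asserted_classes[0]
            minted[first] = minted.get(first, 0) + 1
        expected: dict = {}
        oracle(expr, 1, expected)
        assert minted == {k: v for k, v in expected.items() if v}


def _reachable(node):
    """Nodes the expansion actually visits: it stops at `not` (the whole
    negated subtree becomes one hybrid entry)."""
    yield node
    if node.kind == "not":
        return
    if node.filler is not None:
        yield from _reachable(node.filler)
    for op in node.operands:
        yield from _reachable(op)


def test_expansion_accounts_for_every_node(registry):
    """Node accounting: every reachable `exactly` becomes an exact-count
    hybrid entry and every reachable `not` an absence entry — nothing is
    silently dropped (residue covers the rest)."""
    rng = random.Random(8)
    for _ in range(50):
        expr = random_expression(rng, 3)
        result = expand_to_abox(expr, registry, "EX:multicellular-organism")
        reachable = list(_reachable(expr))
        assert len([h for h in result.hybrid_assertions
                    if h.kind == "exact-count"]) == \
            sum(1 for n in reachable if n.kind == "exactly")
        assert len([h for h in result.hybrid_assertions
                    if h.kind == "absence"]) == \
            sum(1 for n in reachable if n.kind == "not")


def test_rollup_of_quality_pkg_inverts_to_eq(registry):
    pkg = create_description(registry, "MA:0000261")
    pkg.add_quality(pkg.odu_uri, "PATO:0000322", CAT_COLOR)
    rolled = rollup_to_tbox(pkg, pkg.odu_uri)
    expr = some(HAS_PART, rolled.expression)
    assert expression_to_eq(expr, registry) == \
        EQStatement(entity="MA:0000261", quality="PATO:0000322")


def test_rollup_single_instance_is_atomic(registry):
    pkg = create_description(registry, "UBERON:0000972")
    assert rollup_to_tbox(pkg, pkg.odu_uri).expression == atomic("UBERON:0000972")


def test_rollup_unknown_root(registry):
    pkg = create_description(registry, "UBERON:0000972")
    with pytest.raises(UnknownReferenceError):
        rollup_to_tbox(pkg, "https://example.org/nowhere")


def test_rollup_skips_measurements_and_reports_them(registry):
    pkg = build_organism_pkg(registry)
    rolled = rollup_to_tbox(pkg, pkg.odu_uri, closed_world=True)
    assert len(rolled.skipped_measurements) == 1
    text = serialize_manchester(rolled.expression, registry)
    assert "84.3" not in text and "milligram" not in text


def test_closed_world_rollup_emits_exact_cardinalities(registry):
    pkg = create_description(registry, "UBERON:6000004")
    pkg.add_part(pkg.odu_uri, "UBERON:0000972")
    pkg.add_part(pkg.odu_uri, "UBERON:0000972")
    text = serialize_manchester(
        rollup_to_tbox(pkg, pkg.odu_uri, closed_world=True).expression, registry)
    assert "has part exactly 2 antenna" in text


def test_expand_rollup_roundtrip_modulo_uris(registry):
    """expand(rollup(pkg, closed_world)) is isomorphic to pkg up to URI
    renaming for measurement-free descriptions (100 random cases)."""
    for seed in range(100):
        pkg = generate_pkg(GeneratorParams(seed=seed, p_measurement=0.0), registry)
        rolled = rollup_to_tbox(pkg, pkg.odu_uri, closed_world=True)
        result = expand_to_abox(rolled.expression, registry,
                                pkg.instances[pkg.odu_uri].asserted_classes[0])
        assert result.residue == []
        assert partonomy_signature(pkg, pkg.odu_uri) == \
            partonomy_signature(result.pkg, result.pkg.odu_uri)


def test_absence_variants(registry):
    hybrid = build_absence("hybrid", registry, "https://example.org/i/abdomen-1",
                           "EX:ovipositor")
    assert isinstance(hybrid, HybridPattern)
    assert hybrid.dl_compliant
    assert serialize_manchester(hybrid.expression, registry) == \
        "not ( has part some ovipositor )"
    abox = build_absence("abox-only", registry, "https://example.org/i/abdomen-1",
                         "EX:ovipositor")
    assert isinstance(abox, AboxOnlyPattern)
    assert not abox.dl_compliant
    assert len(abox.triples) == 1


def test_exact_count_variants(registry):
    hybrid = build_exact_count("hybrid", registry, "https://example.org/i/head-1",
                               "EX:ocellus", 3)
    assert hybrid.dl_compliant
    assert serialize_manchester(hybrid.expression, registry) == \
        "has component exactly 3 ocellus"
    zero = build_exact_count("hybrid", registry, "https://example.org/i/head-1",
                             "EX:ocellus", 0)
    assert zero.expression.cardinality == 0
    abox = build_exact_count("abox-only", registry, "https://example.org/i/head-1",
                             "EX:ocellus", 3)
    assert not abox.dl_compliant
    preds = {str(p) for s, p, o in abox.triples}
    assert any(p.endswith("towards-class") for p in preds)
    with pytest.raises(DomainError):
        build_exact_count("hybrid", registry, "https://example.org/i/head-1",
                          "EX:ocellus", -1)


def test_variant_flags_agree_with_dl_compliance_checker(registry):
    """Cross-module consistency: the compliance checker reproduces the
    flags the builders return, for all four variant outputs."""
    bearer = "https://example.org/i/x"
    for pattern in (build_absence("hybrid", registry, bearer, "EX:ovipositor"),
                    build_absence("abox-only", registry, bearer, "EX:ovipositor"),
                    build_exact_count("hybrid", registry, bearer, "EX:ocellus", 3),
                    build_exact_count("abox-only", registry, bearer, "EX:ocellus", 3)):
        ok, offending = dl_compliance(pattern, registry)
        assert ok == pattern.dl_compliant
        if not ok:
            assert offending


def test_identical_hybrid_patterns_unify_across_descriptions(registry):
    a = build_absence("hybrid", registry, "https://example.org/i/a", "EX:ovipositor")
    b = build_absence("hybrid", registry, "https://example.org/i/b", "EX:ovipositor")
    assert a.class_uri == b.class_uri


def test_hybrid_pattern_owl_triples_use_blank_nodes_only_in_tbox(registry):
    pattern = build_absence("hybrid", registry, "https://example.org/i/a",
                            "EX:ovipositor")
    triples = pattern.to_triples(registry)
    subject, _, obj = pattern.class_assertion_triple()
    assert str(subject) == "https://example.org/i/a"
    assert str(obj) == pattern.class_uri


@pytest.mark.parametrize("direction,bound", [
    ("increased", "exclusive-lower"),
    ("decreased", "exclusive-upper"),
])
def test_comparative_grounding(direction, bound):
    stmt = ComparativeStatement(quality_kind="EX:length-quality",
                                bearer_class="EX:abdomen", direction=direction,
                                reference_value=Decimal("2.6"),
                                reference_unit="EX:millimetre")
    direct = comparative_to_direct(stmt)
    assert direct.bound_kind == bound
    assert direct.bound_value == Decimal("2.6")
    assert direct.unit == "EX:millimetre"
    assert direct.bearer_class == "EX:abdomen"


def test_comparative_without_reference_is_unresolvable():
    stmt = ComparativeStatement(quality_kind="EX:length-quality",
                                bearer_class="EX:abdomen", direction="increased")
    with pytest.raises(UnresolvableComparativeError, match="reference"):
        comparative_to_direct(stmt)
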