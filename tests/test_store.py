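"""Fragmentation, union identity, views, metadata, nanopubs, revisions."""

import random
from collections import Counter
from decimal import Decimal

import pytest
from rdflib import Literal

from phenokg.errors import (DomainError, PreconditionError, StalenessError,
                            UnknownReferenceError)
from phenokg.pkg import create_description
from phenokg.store import (DataView, MetadataRecord, Store, fragment,
                           nanopub_to_trig, parse_trig_quads, union_graphs)
from phenokg.synth import GeneratorParams, build_organism_pkg, generate_pkg
from phenokg.vocab import (CAT_INSTANTIATION, CAT_PARTHOOD, CAT_SHAPE, CAT_WEIGHT,
                           HAS_VALUE)


def weight_graph_of(store, desc):
    return next(g for g in store.active_graphs(desc) if g.category == CAT_WEIGHT)


def test_organism_fragments_to_expected_category_multiset(registry):
    """The organism fixture yields two parthood graphs plus one shape and
    one weight graph, and a single instantiation graph for the ODU."""
    pkg = build_organism_pkg(registry)
    graphs = fragment(pkg)
    counts = Counter(g.category for g in graphs)
    assert counts == {CAT_PARTHOOD: 2, CAT_SHAPE: 1, CAT_WEIGHT: 1,
                      CAT_INSTANTIATION: 1}


def test_fresh_description_fragments_to_instantiation_only(registry):
    pkg = create_description(registry, "EX:multicellular-organism")
    graphs = fragment(pkg)
    assert [g.category for g in graphs] == [CAT_INSTANTIATION]


def test_quads_carry_their_graph_uri(registry):
    for g in fragment(build_organism_pkg(registry)):
        assert {str(q[3]) for q in g.quads} == {g.uri}
        assert len(g.quads) == len(g.triples)


def test_descriptive_graph_count_matches_assertion_count_oracle(registry):
    for seed in range(25):
        pkg = generate_pkg(GeneratorParams(seed=seed), registry)
        graphs = fragment(pkg)
        n_descriptive = sum(1 for a in pkg.assertions
                            if a.kind in ("parthood", "quality", "measurement"))
        assert len(graphs) == n_descriptive + 1  # + the ODU instantiation graph


def test_union_fragment_identity(registry):
    """union(fragment(pkg)) returns exactly the description's triple set."""
    assert union_graphs([]) == set()
    pkg = build_organism_pkg(registry)
    assert union_graphs(fragment(pkg)) == pkg.triples()
    for seed in range(200):
        pkg = generate_pkg(GeneratorParams(seed=seed, max_depth=2), registry)
        assert union_graphs(fragment(pkg)) == pkg.triples()


def test_fragmentation_partitions_descriptive_content(registry):
    """Named graphs are pairwise quad-disjoint: the placement policy puts a
    minted instance's type/label triples in the graph of the assertion that
    minted it, and the ODU's in the instantiation graph, so no triple is
    shared at all."""
    for seed in range(20):
        pkg = generate_pkg(GeneratorParams(seed=seed), registry)
        graphs = fragment(pkg)
        seen = set()
        for g in graphs:
            assert not (seen & g.triples)
            seen |= g.triples


def test_graph_uris_are_deterministic(registry):
    a = fragment(build_organism_pkg(registry, seed=3))
    b = fragment(build_organism_pkg(registry, seed=3))
    assert [g.uri for g in a] == [g.uri for g in b]


def test_weight_view_returns_the_measured_value(registry, worked):
    store, keys = worked
    triples = store.apply_view(keys.organism, DataView("w", frozenset([CAT_WEIGHT])))
    values = {str(o) for s, p, o in triples if p == registry.uriref(HAS_VALUE)}
    assert values == {"84.3"}
    units = {o for s, p, o in triples if p == registry.uriref("EX:has-unit")}
    assert units == {registry.uriref("EX:milligram")}


def test_measurement_view_with_closure_supersets_weight_view(registry, worked):
    store, keys = worked
    weight = store.apply_view(keys.organism, DataView("w", frozenset([CAT_WEIGHT])))
    meas = store.apply_view(keys.organism,
                            DataView("m", frozenset(["EX:measurement"]),
                                     use_closure=True))
    assert weight <= meas
    everything = union_graphs(store.active_graphs(keys.organism))
    assert meas <= everything


def test_view_monotone_in_category_set(registry, worked):
    store, keys = worked
    small = store.apply_view(keys.organism, DataView("a", frozenset([CAT_SHAPE])))
    large = store.apply_view(keys.organism,
                             DataView("b", frozenset([CAT_SHAPE, CAT_PARTHOOD])))
    assert small <= large


def test_empty_view_and_unknown_description(registry, worked):
    store, keys = worked
    assert store.apply_view(keys.organism,
                            DataView("v", frozenset(["EX:volume"]))) == set()
    with pytest.raises(UnknownReferenceError):
        store.apply_view("https://example.org/nope", DataView("v", frozenset(["EX:weight"])))


def test_metadata_attachment_and_multi_target(registry, worked):
    store, keys = worked
    shape_graph = next(g for g in store.active_graphs(keys.organism)
                       if g.category == CAT_SHAPE)
    uri = store.attach_metadata(MetadataRecord(
        target_graphs={shape_graph.uri}, agent="tester", date="2021-05-01"))
    assert any(str(s) == shape_graph.uri for s, p, o in store.metadata_graphs[uri])
    parthood = [g.uri for g in store.active_graphs(keys.organism)
                if g.category == CAT_PARTHOOD]
    multi = store.attach_metadata(MetadataRecord(
        target_graphs=set(parthood), agent="tester", date="2021-05-01"))
    subjects = {str(s) for s, p, o in store.metadata_graphs[multi]}
    assert subjects == set(parthood)
    with pytest.raises(UnknownReferenceError):
        store.attach_metadata(MetadataRecord(
            target_graphs={"https://example.org/nope"}, agent="x", date="2021-01-01"))


def test_metadata_record_validation():
    with pytest.raises(DomainError):
        MetadataRecord(target_graphs=set(), agent="x", date="2021-01-01")
    with pytest.raises(ValueError):
        MetadataRecord(target_graphs={"g"}, agent="x", date="not a date")


def test_nanopublication_export_and_trig_roundtrip(registry, worked):
    store, keys = worked
    wg = weight_graph_of(store, keys.organism)
    np = store.export_nanopublication(wg.uri)
    uris = {np.head_uri, np.assertion.uri, np.provenance_uri, np.pubinfo_uri}
    assert len(uris) == 4
    head_objects = {str(o) for s, p, o in np.head}
    assert {np.assertion.uri, np.provenance_uri, np.pubinfo_uri} <= head_objects
    trig = nanopub_to_trig(registry, np)
    assert parse_trig_quads(trig) == np.quads()


def test_nanopublication_requires_metadata(registry, worked):
    store, keys = worked
    bare = store.active_graphs(keys.flattened_head)[0]
    with pytest.raises(PreconditionError, match="metadata"):
        store.export_nanopublication(bare.uri)


def _revised(graph, suffix, old_value, new_value):
    triples = frozenset(
        (s, p, Literal(Decimal(new_value))) if str(o) == old_value else (s, p, o)
        for s, p, o in graph.triples)
    return graph.with_uri(graph.uri + suffix, triples)


def test_revision_corrects_value_and_keeps_history(registry, worked):
    store, keys = worked
    wg = weight_graph_of(store, keys.organism)
    record = MetadataRecord(target_graphs={wg.uri}, agent="corrector",
                            date="2021-06-01")
    change = store.revise(wg.uri, _revised(wg, "/rev1", "84.3", "48.3"), record)
    view = store.apply_view(keys.organism, DataView("w", frozenset([CAT_WEIGHT])))
    assert {str(o) for s, p, o in view
            if p == registry.uriref(HAS_VALUE)} == {"48.3"}
    # superseded graph retained with its original value
    assert any(str(o) == "84.3" for s, p, o in store.graphs[change.superseded].triples)
    # union identity is preserved on the active graph set
    active = union_graphs(store.active_graphs(keys.organism))
    assert any(str(o) == "48.3" for s, p, o in active)
    assert not any(str(o) == "84.3" for s, p, o in active)


def test_revision_category_mismatch_and_staleness(registry, worked):
    store, keys = worked
    wg = weight_graph_of(store, keys.organism)
    record = MetadataRecord(target_graphs={wg.uri}, agent="x", date="2021-06-01")
    wrong_cat = _revised(wg, "/bad", "84.3", "48.3")
    object.__setattr__(wrong_cat, "category", CAT_SHAPE)
    with pytest.raises(DomainError, match="category"):
        store.revise(wg.uri, wrong_cat, record)
    store.revise(wg.uri, _revised(wg, "/rev1", "84.3", "48.3"), record)
    with pytest.raises(StalenessError):
        store.revise(wg.uri, _revised(wg, "/rev2", "84.3", "47.0"), record)


def test_two_revisions_walkable_newest_to_oldest(registry, worked):
    store, keys = worked
    wg = weight_graph_of(store, keys.organism)
    record = MetadataRecord(target_graphs={wg.uri}, agent="x", date="2021-06-01")
    r1 = _revised(wg, "/rev1", "84.3", "48.3")
    store.revise(wg.uri, r1, record)
    r2 = _revised(r1, "/rev2", "48.3", "47.0")
    store.revise(r1.uri, r2,
                 MetadataRecord(target_graphs={r1.uri}, agent="x", date="2021-06-02"))
    assert store.supersedes_chain(r2.uri) == [r2.uri, r1.uri, wg.uri]
    assert len(store.revisions) == 2


def test_store_save_load_roundtrip(registry, worked, tmp_path):
    store, keys = worked
    store.save(tmp_path / "store")
    loaded = Store.load(tmp_path / "store", registry)
    assert set(loaded.descriptions) == set(store.descriptions)
    for desc in store.descriptions:
        assert union_graphs(loaded.active_graphs(desc)) == \
            union_graphs(store.active_graphs(desc))
    # metadata records survive, so nanopub export still works after reload
    wg = weight_graph_of(loaded, keys.organism)
    assert loaded.export_nanopublication(wg.uri).assertion.uri == wg.uri
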