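"""Named-graph fragmentation, data views, metadata, nanopublications, revisions.

A phenotype knowledge graph decomposes into its smallest units of empirical
information: one *descriptive named graph* per descriptive assertion
(parthood link, quality, or measurement).  Turning the triples into quads —
tagging each triple with its graph's URI — makes every single observation
individually addressable: it can carry its own metadata, be exported as a
nanopublication, be superseded by a corrected version, or be selected into
a data view ("all weight measurements", "all measurements").  The union of
a description's named graphs returns exactly the original triple set.

Placement policy: a minted instance's type/label triples live in the named
graph of the assertion that minted it (each graph is self-describing); the
ODU's own type/label triples live in a dedicated instantiation graph.  The
triple typing a named graph with its perceptual-category class is emitted
in the TriG default graph, *outside* the named graph, so fragmentation and
union stay exact inverses.
"""

from __future__ import annotations

import datetime as _dt
import json
import pathlib
from dataclasses import dataclass, field, replace

from rdflib import Dataset, Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF

from .errors import (DomainError, PreconditionError, StalenessError,
                     UnknownReferenceError)
from .pkg import PhenotypeKnowledgeGraph
from .vocab import CAT_INSTANTIATION, EX_BASE, TermRegistry

Triple = tuple[URIRef, URIRef, object]

# Fixture provenance vocabulary (agent / date / source / instrument plus
# free fields); mapping to standard provenance ontologies is a
# serialization concern, not core semantics.
PROV = Namespace(EX_BASE + "prov/")
NP = Namespace("http://www.nanopub.org/nschema#")


@dataclass(frozen=True)
class DescriptiveNamedGraph:
    """One descriptive statement as a named set of triples."""

    uri: str
    category: str
    subject_part: str
    triples: frozenset[Triple]

    @property
    def quads(self) -> frozenset[tuple]:
        g = URIRef(self.uri)
        return frozenset((s, p, o, g) for s, p, o in self.triples)

    def with_uri(self, new_uri: str,
                 triples: frozenset[Triple] | None = None) -> "DescriptiveNamedGraph":
        return replace(self, uri=new_uri,
                       triples=self.triples if triples is None else frozenset(triples))


@dataclass
class MetadataRecord:
    """Statements about one or more named graphs: who, when, from what source,
    with which instrument; ``free_fields`` covers micro-publication payloads
    (reserved keys ``text`` and ``media``) and anything else."""

    target_graphs: set[str]
    agent: str
    date: str
    source: str | None = None
    instrument: str | None = None
    free_fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.target_graphs:
            raise DomainError("metadata record must target at least one graph")
        _dt.date.fromisoformat(self.date[:10])  # raises ValueError if unparseable

    def triples_for(self, target: str) -> set[Triple]:
        t = URIRef(target)
        out = {(t, PROV.agent, Literal(self.agent)), (t, PROV.date, Literal(self.date))}
        if self.source is not None:
            out.add((t, PROV.source, Literal(self.source)))
        if self.instrument is not None:
            out.add((t, PROV.instrument, Literal(self.instrument)))
        for key, value in sorted(self.free_fields.items()):
            out.add((t, PROV[key], Literal(value)))
        return out


@dataclass(frozen=True)
class DataView:
    """A selection of named-graph categories for exploring descriptions."""

    name: str
    categories: frozenset[str]
    use_closure: bool = False


@dataclass(frozen=True)
class ChangeRecord:
    superseded: str
    replacement: str
    record: MetadataRecord

    def __post_init__(self):
        if self.superseded == self.replacement:
            raise DomainError("a revision must mint a fresh graph URI")


@dataclass(frozen=True)
class Nanopublication:
    """Conventional four-graph bundle: head, assertion, provenance, pubinfo."""

    uri: str
    head_uri: str
    assertion: DescriptiveNamedGraph
    provenance_uri: str
    provenance: frozenset[Triple]
    pubinfo_uri: str
    pubinfo: frozenset[Triple]

    @property
    def head(self) -> frozenset[Triple]:
        np = URIRef(self.uri)
        return frozenset({
            (np, RDF.type, NP.Nanopublication),
            (np, NP.hasAssertion, URIRef(self.assertion.uri)),
            (np, NP.hasProvenance, URIRef(self.provenance_uri)),
            (np, NP.hasPublicationInfo, URIRef(self.pubinfo_uri)),
        })

    def named_graphs(self) -> list[tuple[str, frozenset[Triple]]]:
        return [(self.head_uri, self.head),
                (self.assertion.uri, self.assertion.triples),
                (self.provenance_uri, self.provenance),
                (self.pubinfo_uri, self.pubinfo)]

    def quads(self) -> set[tuple]:
        return {(s, p, o, URIRef(g)) for g, triples in self.named_graphs()
                for s, p, o in triples}


# ---------------------------------------------------------------------------
# fragmentation


def _local(registry: TermRegistry, curie: str) -> str:
    return registry.label_of(curie).replace(" ", "-")


def fragment(pkg: PhenotypeKnowledgeGraph,
             description_uri: str | None = None) -> list[DescriptiveNamedGraph]:
    """Split a PKG into descriptive named graphs plus one instantiation graph.

    Exactly one graph per descriptive assertion; each carries that
    assertion's triples plus the type/label triples of the instance it
    minted.  Graph URIs are deterministic in
    (description URI, category, subject part, ordinal).
    """
    reg = pkg.registry
    base = description_uri or pkg.odu_uri + "/description"
    minted_extras: dict[str, list[Triple]] = {}
    odu_triples: set[Triple] = set()
    for a in pkg.assertions:
        if a.kind in ("instantiation", "labeling"):
            ts = pkg.assertion_triples(a)
            if a.subject == pkg.odu_uri:
                odu_triples.update(ts)
            else:
                minted_extras.setdefault(a.subject, []).extend(ts)

    graphs: list[DescriptiveNamedGraph] = []
    ordinals: dict[tuple[str, str], int] = {}
    for a in pkg.descriptive_assertions():
        key = (a.category, a.subject)
        ordinals[key] = ordinals.get(key, 0) + 1
        uri = (f"{base}/graph/{_local(reg, a.category)}/"
               f"{a.subject.rsplit('/', 1)[-1]}/{ordinals[key]}")
        triples = set(pkg.assertion_triples(a))
        triples.update(minted_extras.get(a.object, ()))
        graphs.append(DescriptiveNamedGraph(uri=uri, category=a.category,
                                            subject_part=a.subject,
                                            triples=frozenset(triples)))
    inst_uri = f"{base}/graph/instantiation/odu/1"
    graphs.append(DescriptiveNamedGraph(uri=inst_uri, category=CAT_INSTANTIATION,
                                        subject_part=pkg.odu_uri,
                                        triples=frozenset(odu_triples)))
    return graphs


def union_graphs(graphs: list[DescriptiveNamedGraph]) -> set[Triple]:
    """Drop the graph component: the union of all named graphs of a
    description is the description's plain triple set."""
    out: set[Triple] = set()
    for g in graphs:
        out |= g.triples
    return out


# ---------------------------------------------------------------------------
# the store


class Store:
    """In-memory quad store: descriptions, their named graphs, metadata,
    and revision history."""

    def __init__(self, registry: TermRegistry):
        self.registry = registry
        self.graphs: dict[str, DescriptiveNamedGraph] = {}
        self.descriptions: dict[str, list[str]] = {}   # active graph URIs, ordered
        self.superseded: dict[str, str] = {}           # superseded -> replacement
        self.metadata: list[MetadataRecord] = []
        self.metadata_graphs: dict[str, frozenset[Triple]] = {}
        self.revisions: list[ChangeRecord] = []
        self.patterns: dict[str, object] = {}          # optional worked-example extras
        self._meta_counter = 0

    # -- descriptions -----------------------------------------------------

    def add_description(self, pkg: PhenotypeKnowledgeGraph,
                        description_uri: str | None = None) -> str:
        desc = description_uri or pkg.odu_uri + "/description"
        if desc in self.descriptions:
            raise DomainError(f"description {desc} already stored")
        gs = fragment(pkg, desc)
        for g in gs:
            self.graphs[g.uri] = g
        self.descriptions[desc] = [g.uri for g in gs]
        return desc

    def active_graphs(self, description: str) -> list[DescriptiveNamedGraph]:
        if description not in self.descriptions:
            raise UnknownReferenceError(f"unknown description {description!r}")
        return [self.graphs[u] for u in self.descriptions[description]]

    def description_of(self, graph_uri: str) -> str | None:
        for desc, uris in self.descriptions.items():
            if graph_uri in uris:
                return desc
        return None

    # -- data views -------------------------------------------------------

    def apply_view(self, description: str, view: DataView) -> set[Triple]:
        """Union of the description's active graphs whose category falls in
        the view (subclass-closed when ``use_closure`` is set)."""
        wanted: set[str] = set()
        for c in view.categories:
            self.registry.resolve(c)
            wanted |= self.registry.subclass_closure(c) if view.use_closure else {c}
        return union_graphs([g for g in self.active_graphs(description)
                             if g.category in wanted])

    # -- metadata ---------------------------------------------------------

    def attach_metadata(self, record: MetadataRecord) -> str:
        """Store a metadata record as its own named graph; returns its URI."""
        for t in record.target_graphs:
            if t not in self.graphs:
                raise UnknownReferenceError(f"metadata targets unknown graph {t!r}")
        self.metadata.append(record)
        self._meta_counter += 1
        uri = f"{EX_BASE}metadata-graph/{self._meta_counter}"
        triples: set[Triple] = set()
        for t in sorted(record.target_graphs):
            triples |= record.triples_for(t)
        self.metadata_graphs[uri] = frozenset(triples)
        return uri

    def records_for(self, graph_uri: str) -> list[MetadataRecord]:
        return [r for r in self.metadata if graph_uri in r.target_graphs]

    # -- nanopublications -------------------------------------------------

    def export_nanopublication(self, graph_uri: str,
                               agent: str = "phenokg") -> Nanopublication:
        """Bundle one descriptive graph with its provenance as a
        four-graph nanopublication; requires ≥1 metadata record."""
        if graph_uri not in self.graphs:
            raise UnknownReferenceError(f"unknown graph {graph_uri!r}")
        records = self.records_for(graph_uri)
        if not records:
            raise PreconditionError(
                f"graph {graph_uri} has no metadata; a nanopublication "
                "requires provenance")
        g = self.graphs[graph_uri]
        base = graph_uri + "/nanopub"
        np = URIRef(base)
        prov_triples: set[Triple] = set()
        for r in records:
            prov_triples |= r.triples_for(graph_uri)
        stamp = max(r.date for r in records)
        pubinfo: set[Triple] = {(np, PROV.agent, Literal(agent)),
                                (np, PROV.date, Literal(stamp))}
        return Nanopublication(uri=base, head_uri=base + "/Head", assertion=g,
                               provenance_uri=base + "/provenance",
                               provenance=frozenset(prov_triples),
                               pubinfo_uri=base + "/pubinfo",
                               pubinfo=frozenset(pubinfo))

    # -- revisions --------------------------------------------------------

    def revise(self, graph_uri: str, replacement: DescriptiveNamedGraph,
               record: MetadataRecord) -> ChangeRecord:
        """Replace an active graph; the superseded one stays in history."""
        if graph_uri in self.superseded:
            raise StalenessError(f"graph {graph_uri} is already superseded")
        desc = self.description_of(graph_uri)
        if desc is None:
            raise UnknownReferenceError(f"graph {graph_uri!r} is not active "
                                        "in any description")
        old = self.graphs[graph_uri]
        if replacement.uri in self.graphs:
            raise DomainError(f"replacement URI {replacement.uri} already exists")
        if replacement.category != old.category:
            raise DomainError(
                f"replacement category {replacement.category} does not match "
                f"{old.category}")
        self.graphs[replacement.uri] = replacement
        uris = self.descriptions[desc]
        uris[uris.index(graph_uri)] = replacement.uri
        self.superseded[graph_uri] = replacement.uri
        change = ChangeRecord(superseded=graph_uri, replacement=replacement.uri,
                              record=record)
        self.revisions.append(change)
        # the change itself is documented in RDF, in its own metadata graph
        self.metadata.append(replace_targets(record, {replacement.uri}))
        self._meta_counter += 1
        meta_uri = f"{EX_BASE}metadata-graph/{self._meta_counter}"
        triples = set(record.triples_for(replacement.uri))
        triples.add((URIRef(replacement.uri), PROV.supersedes, URIRef(graph_uri)))
        self.metadata_graphs[meta_uri] = frozenset(triples)
        return change

    def supersedes_chain(self, graph_uri: str) -> list[str]:
        """Walk newest → oldest from an active graph URI."""
        chain = [graph_uri]
        back = {v: k for k, v in self.superseded.items()}
        while chain[-1] in back:
            chain.append(back[chain[-1]])
        return chain

    # -- serialization ----------------------------------------------------

    def description_quads(self, description: str, include_history: bool = False):
        uris = list(self.descriptions[description])
        if include_history:
            uris += [u for u, r in self.superseded.items()
                     if self.description_of(r) == description
                     or r in uris or any(r in self.supersedes_chain(a) for a in uris)]
        out = set()
        for u in dict.fromkeys(uris):
            out |= self.graphs[u].quads
        return out

    def description_to_trig(self, description: str) -> str:
        graphs = self.active_graphs(description)
        default_triples = {(URIRef(g.uri), RDF.type, self.registry.uriref(g.category))
                           for g in graphs}
        return serialize_trig(self.registry,
                              [(g.uri, g.triples) for g in graphs],
                              default_triples)

    def save(self, path: str | pathlib.Path) -> None:
        """Persist as a directory of TriG files plus a JSON manifest."""
        path = pathlib.Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "descriptions": {},
            "superseded": self.superseded,
            "graph_meta": {u: {"category": g.category, "subject_part": g.subject_part}
                           for u, g in sorted(self.graphs.items())},
            "revisions": [{"superseded": c.superseded, "replacement": c.replacement,
                           "agent": c.record.agent, "date": c.record.date}
                          for c in self.revisions],
            "metadata": [{"target_graphs": sorted(r.target_graphs),
                          "agent": r.agent, "date": r.date, "source": r.source,
                          "instrument": r.instrument,
                          "free_fields": r.free_fields}
                         for r in self.metadata],
        }
        for i, (desc, uris) in enumerate(sorted(self.descriptions.items()), 1):
            fname = f"description-{i:03d}.trig"
            manifest["descriptions"][desc] = {"file": fname, "graphs": uris}
            quads = [(u, self.graphs[u].triples) for u in uris]
            (path / fname).write_text(serialize_trig(self.registry, quads, set()))
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | pathlib.Path, registry: TermRegistry) -> "Store":
        path = pathlib.Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        store = cls(registry)
        for desc, entry in manifest["descriptions"].items():
            ds = Dataset()
            ds.parse(path / entry["file"], format="trig")
            for uri in entry["graphs"]:
                meta = manifest["graph_meta"][uri]
                triples = frozenset(
                    (s, p, o) for s, p, o in ds.graph(URIRef(uri)))
                store.graphs[uri] = DescriptiveNamedGraph(
                    uri=uri, category=meta["category"],
                    subject_part=meta["subject_part"], triples=triples)
            store.descriptions[desc] = list(entry["graphs"])
        store.superseded = dict(manifest.get("superseded", {}))
        for r in manifest.get("metadata", []):
            store.metadata.append(MetadataRecord(
                target_graphs=set(r["target_graphs"]), agent=r["agent"],
                date=r["date"], source=r.get("source"),
                instrument=r.get("instrument"),
                free_fields=dict(r.get("free_fields") or {})))
        return store


def replace_targets(record: MetadataRecord, targets: set[str]) -> MetadataRecord:
    return MetadataRecord(target_graphs=set(targets), agent=record.agent,
                          date=record.date, source=record.source,
                          instrument=record.instrument,
                          free_fields=dict(record.free_fields))


# ---------------------------------------------------------------------------
# quad serialization


def _nt_lines(triples) -> list[str]:
    g = Graph()
    for t in triples:
        g.add(t)
    return sorted(line for line in g.serialize(format="nt").splitlines() if line.strip())


def serialize_trig(registry: TermRegistry,
                   named: list[tuple[str, frozenset[Triple]]],
                   default_triples: set[Triple]) -> str:
    """Deterministic TriG: prefix header, default graph, then named graphs
    ordered by URI with lexicographically sorted triples."""
    out = [f"@prefix {p}: <{b}> ." for p, b in sorted(registry.prefix_map.items())]
    out.append("")
    if default_triples:
        out.extend(_nt_lines(default_triples))
        out.append("")
    for uri, triples in sorted(named, key=lambda x: x[0]):
        out.append(f"<{uri}> {{")
        out.extend("    " + line for line in _nt_lines(triples))
        out.append("}")
        out.append("")
    return "\n".join(out)


def serialize_nquads(named: list[tuple[str, frozenset[Triple]]]) -> str:
    lines = []
    for uri, triples in named:
        for line in _nt_lines(triples):
            lines.append(line[:-2] + f" <{uri}> .")
    return "\n".join(sorted(lines)) + "\n"


def parse_trig_quads(text: str) -> set[tuple]:
    """Parse TriG text into a set of (s, p, o, graph URIRef) quads."""
    ds = Dataset()
    ds.parse(data=text, format="trig")
    return {(s, p, o, g.identifier) for g in ds.graphs()
            if g.identifier != ds.default_graph.identifier
            for s, p, o in g}


def nanopub_to_trig(registry: TermRegistry, np: Nanopublication) -> str:
    return serialize_trig(registry, np.named_graphs(), set())
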