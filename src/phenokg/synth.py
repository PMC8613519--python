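"""Deterministic synthetic descriptions and the canned worked examples.

The generator produces random but structurally valid phenotype knowledge
graphs — a partonomy of bounded depth and branching with Bernoulli-attached
qualities and measurements — so that every other module can be exercised
without external data.  Randomness comes from Python's Mersenne-Twister
``random.Random`` seeded explicitly; identical parameters and seed yield
byte-identical canonical Turtle on any platform.  The generator targets
structural coverage, not biological realism.

:func:`build_worked_examples` assembles the small fixture descriptions used
throughout the documentation and tests: an insect head with a flattened
shape and two antennae; a multicellular organism whose head bears an
antenna, described with a flattened shape and a measured live weight of
84.3 milligrams (fragmented into named graphs with per-statement metadata);
an eye with a red color quality; and the absence / exact-count fixtures
(an abdomen lacking an ovipositor, a head with exactly three ocelli) in
both their ABox-only and hybrid modelling variants.
"""

from __future__ import annotations

import importlib.resources
import random
from dataclasses import dataclass, field
from decimal import Decimal

from .convert import build_absence, build_exact_count
from .errors import DomainError
from .pkg import MintingPolicy, PhenotypeKnowledgeGraph, create_description
from .store import MetadataRecord, Store
from .vocab import (CAT_COLOR, CAT_LENGTH, CAT_PARTHOOD, CAT_SHAPE, CAT_WEIGHT,
                    TermRegistry)

DEFAULT_CLASS_POOL = ("UBERON:6000004", "UBERON:0000972", "MA:0000261", "EX:head",
                      "EX:abdomen", "EX:ocellus", "EX:mandible", "EX:scape",
                      "EX:pedicel", "EX:vertex")
DEFAULT_QUALITY_POOL = (("PATO:0002254", CAT_SHAPE), ("PATO:0000322", CAT_COLOR),
                        ("EX:yellow", CAT_COLOR), ("EX:dark-brown", CAT_COLOR))
DEFAULT_MEASUREMENT_KINDS = (
    ("EX:live-weight", "EX:milligram", (1.0, 200.0), CAT_WEIGHT),
    ("EX:length-quality", "EX:millimetre", (0.5, 30.0), CAT_LENGTH),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs for the random description generator.

    ``max_depth`` bounds the partonomy depth below the root; ``branching``
    bounds the child count drawn per node; ``p_quality`` /
    ``p_measurement`` are per-node Bernoulli attachment probabilities.
    Measurement values are drawn uniformly from the kind's range and
    rounded to one decimal place (the precision of the worked examples).
    """

    seed: int
    max_depth: int = 3
    branching: int = 2
    p_quality: float = 0.4
    p_measurement: float = 0.3
    root_class: str = "EX:multicellular-organism"
    class_pool: tuple[str, ...] = DEFAULT_CLASS_POOL
    quality_pool: tuple[tuple[str, str], ...] = DEFAULT_QUALITY_POOL
    measurement_kinds: tuple = DEFAULT_MEASUREMENT_KINDS

    def __post_init__(self):
        if self.max_depth < 0 or self.branching < 0:
            raise DomainError("max_depth and branching must be non-negative")
        for p, name in ((self.p_quality, "p_quality"),
                        (self.p_measurement, "p_measurement")):
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1]")
        if self.p_quality > 0 and not self.quality_pool:
            raise DomainError("p_quality > 0 requires a non-empty quality pool")
        if self.p_measurement > 0 and not self.measurement_kinds:
            raise DomainError("p_measurement > 0 requires measurement kinds")
        if self.max_depth > 0 and self.branching > 0 and not self.class_pool:
            raise DomainError("part generation requires a non-empty class pool")


def generate_pkg(params: GeneratorParams,
                 registry: TermRegistry) -> PhenotypeKnowledgeGraph:
    """Draw one random description; fully deterministic given the seed."""
    rng = random.Random(params.seed)
    pkg = create_description(registry, params.root_class,
                             minting=MintingPolicy(seed=params.seed))

    def decorate(uri: str) -> None:
        if rng.random() < params.p_quality:
            quality, category = rng.choice(params.quality_pool)
            pkg.add_quality(uri, quality, category)
        if rng.random() < params.p_measurement:
            kind, unit, (lo, hi), category = rng.choice(params.measurement_kinds)
            value = round(rng.uniform(lo, hi), 1)
            pkg.add_measurement(uri, kind, value, unit, category)

    def grow(uri: str, depth: int) -> None:
        decorate(uri)
        if depth >= params.max_depth:
            return
        for _ in range(rng.randint(0, params.branching)):
            child = pkg.add_part(uri, rng.choice(params.class_pool))
            grow(child, depth + 1)

    grow(pkg.odu_uri, 0)
    return pkg


# ---------------------------------------------------------------------------
# worked examples


WORKED_HEAD_AXIOM = ("insect head and ( bearer of some flattened ) "
                     "and ( has part exactly 2 antenna )")
"""Reconstruction of the flattened-head axiom: an insect head with a
flattened shape quality that has exactly two antennae as parts.  Expanding
it must mint one insect-head instance, one flattened quality, two antenna
instances."""

OCELLUS_COUNT_EXPRESSION = "has component exactly 3 ocellus"
ABSENCE_EXPRESSION = "not ( has part some ovipositor )"


def head_color_expression() -> str:
    """A richly nested head-coloration character in Manchester syntax,
    shipped as a parser stress case."""
    return (importlib.resources.files("phenokg") / "data" /
            "head_color_statement.txt").read_text().strip()


@dataclass
class WorkedExampleKeys:
    """Description URIs of the canned fixtures inside the returned store."""

    flattened_head: str
    organism: str
    eye_red: str
    abdomen: str
    ocellus_head: str
    light_organism: str


def build_flattened_head_pkg(registry: TermRegistry,
                             seed: int = 0) -> PhenotypeKnowledgeGraph:
    """Insect head, flattened shape, two antenna instances (ABox form)."""
    pkg = create_description(registry, "UBERON:6000004",
                             minting=MintingPolicy(seed=seed))
    pkg.add_quality(pkg.odu_uri, "PATO:0002254", CAT_SHAPE)
    pkg.add_part(pkg.odu_uri, "UBERON:0000972")
    pkg.add_part(pkg.odu_uri, "UBERON:0000972")
    return pkg


def build_organism_pkg(registry: TermRegistry, seed: int = 1,
                       weight_mg="84.3") -> PhenotypeKnowledgeGraph:
    """Multicellular organism → insect head → antenna partonomy, with a
    flattened shape and a measured live weight (default 84.3 mg)."""
    pkg = create_description(registry, "EX:multicellular-organism",
                             minting=MintingPolicy(seed=seed))
    head = pkg.add_part(pkg.odu_uri, "UBERON:6000004")
    pkg.add_part(head, "UBERON:0000972")
    pkg.add_quality(pkg.odu_uri, "PATO:0002254", CAT_SHAPE)
    pkg.add_measurement(pkg.odu_uri, "EX:live-weight", Decimal(str(weight_mg)),
                        "EX:milligram", CAT_WEIGHT)
    return pkg


def build_worked_examples(registry: TermRegistry) -> tuple[Store, WorkedExampleKeys]:
    """Populate a store with the canned worked-example descriptions.

    The organism description gets the three metadata attachments of the
    worked metadata example: one record on the shape graph, one on the
    weight-measurement graph, and a single record targeting the union of
    the two parthood graphs.
    """
    store = Store(registry)

    head_pkg = build_flattened_head_pkg(registry, seed=10)
    flattened_head = store.add_description(head_pkg)

    organism_pkg = build_organism_pkg(registry, seed=11)
    organism = store.add_description(organism_pkg)
    by_cat: dict[str, list[str]] = {}
    for g in store.active_graphs(organism):
        by_cat.setdefault(g.category, []).append(g.uri)
    store.attach_metadata(MetadataRecord(
        target_graphs=set(by_cat[CAT_SHAPE]), agent="observer-1",
        date="2021-03-01", instrument="stereo microscope"))
    store.attach_metadata(MetadataRecord(
        target_graphs=set(by_cat[CAT_WEIGHT]), agent="observer-1",
        date="2021-03-01", instrument="precision balance"))
    store.attach_metadata(MetadataRecord(
        target_graphs=set(by_cat[CAT_PARTHOOD]), agent="observer-2",
        date="2021-03-02", source="specimen vouchered as EX-0001"))

    eye_pkg = create_description(registry, "MA:0000261",
                                 minting=MintingPolicy(seed=12))
    eye_pkg.add_quality(eye_pkg.odu_uri, "PATO:0000322", CAT_COLOR)
    eye_red = store.add_description(eye_pkg)

    abdomen_pkg = create_description(registry, "EX:abdomen",
                                     minting=MintingPolicy(seed=13))
    abdomen = store.add_description(abdomen_pkg)
    store.patterns["absence-abox"] = build_absence(
        "abox-only", registry, abdomen_pkg.odu_uri, "EX:ovipositor")
    store.patterns["absence-hybrid"] = build_absence(
        "hybrid", registry, abdomen_pkg.odu_uri, "EX:ovipositor")

    ocellus_pkg = create_description(registry, "UBERON:6000004",
                                     minting=MintingPolicy(seed=14))
    for _ in range(3):
        ocellus_pkg.add_part(ocellus_pkg.odu_uri, "EX:ocellus")
    ocellus_head = store.add_description(ocellus_pkg)
    store.patterns["count-abox"] = build_exact_count(
        "abox-only", registry, ocellus_pkg.odu_uri, "EX:ocellus", 3)
    store.patterns["count-hybrid"] = build_exact_count(
        "hybrid", registry, ocellus_pkg.odu_uri, "EX:ocellus", 3)

    light_pkg = build_organism_pkg(registry, seed=15, weight_mg="5.0")
    light_organism = store.add_description(light_pkg)

    keys = WorkedExampleKeys(flattened_head=flattened_head, organism=organism,
                             eye_red=eye_red, abdomen=abdomen,
                             ocellus_head=ocellus_head,
                             light_organism=light_organism)
    return store, keys
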