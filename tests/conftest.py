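import random

import pytest

from phenokg.manchester import and_, atomic, exactly, not_, some
from phenokg.synth import build_worked_examples
from phenokg.vocab import build_fixture_registry


@pytest.fixture(scope="session")
def registry():
    return build_fixture_registry()


@pytest.fixture()
def worked(registry):
    """Fresh worked-example store + description keys per test."""
    return build_worked_examples(registry)


ANATOMY = ("UBERON:6000004", "UBERON:0000972", "MA:0000261", "EX:ocellus",
           "EX:mandible", "EX:abdomen", "EX:scape")
QUALITIES = ("PATO:0002254", "PATO:0000322", "EX:yellow", "EX:dark-brown")


def random_expression(rng: random.Random, depth: int):
    """Random Manchester-subset tree over the fixture vocabulary.

    Restricted to the part/quality properties the ABox expansion
    instantiates, so the same generator serves parser and conversion tests.
    """
    kinds = ["atomic", "some", "exactly", "and", "not"] if depth > 0 else ["atomic"]
    kind = rng.choice(kinds)
    if kind == "atomic":
        return atomic(rng.choice(ANATOMY))
    if kind == "not":
        return not_(random_expression(rng, depth - 1))
    if kind == "some":
        if rng.random() < 0.3:
            return some("EX:bearer-of", atomic(rng.choice(QUALITIES)))
        filler = atomic(rng.choice(ANATOMY))
        if rng.random() < 0.5:
            filler = and_(filler, random_expression(rng, depth - 1))
        return some("EX:has-part", filler)
    if kind == "exactly":
        return exactly("EX:has-part", rng.randint(0, 3), atomic(rng.choice(ANATOMY)))
    return and_(random_expression(rng, depth - 1), random_expression(rng, depth - 1))


def partonomy_signature(pkg, uri):
    """Order-insensitive structural signature of an instance subtree:
    asserted classes, child-part subtrees, quality class sets.  Independent
    reconstruction straight from the assertion list (not partonomy_tree)."""
    node = pkg.instances[uri]
    children = [a.object for a in pkg.assertions
                if a.kind == "parthood" and a.subject == uri]
    quals = [a.object for a in pkg.assertions
             if a.kind == "quality" and a.subject == uri]
    return (tuple(sorted(node.asserted_classes)),
            tuple(sorted(partonomy_signature(pkg, c) for c in children)),
            tuple(sorted(tuple(sorted(pkg.instances[q].asserted_classes))
                         for q in quals)))
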