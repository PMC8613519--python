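"""Exception hierarchy.

Every error raised by the library derives from :class:`PhenoKGError`, so
callers (including the CLI) can distinguish user/data errors from bugs.
"""

from __future__ import annotations


class PhenoKGError(Exception):
    """Base class for all phenokg errors."""


class UnknownTermError(PhenoKGError, KeyError):
    """A CURIE or label could not be resolved against the term registry."""

    def __init__(self, curie_or_label: str, message: str | None = None):
        self.curie = curie_or_label
        super().__init__(message or f"unknown term: {curie_or_label!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class ManchesterSyntaxError(PhenoKGError, ValueError):
    """Malformed Manchester-syntax text; carries the character position."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class NotEQRepresentableError(PhenoKGError, ValueError):
    """A class expression lies outside the EQ-representable subset."""

    def __init__(self, message: str, offending=None):
        self.offending = offending
        super().__init__(message)


class UnknownReferenceError(PhenoKGError, KeyError):
    """A URI (instance, named graph, description) is not known to the container."""

    def __str__(self) -> str:
        return self.args[0]


class DomainError(PhenoKGError, ValueError):
    """A value violates a domain constraint (non-unit unit, negative count, ...)."""


class StalenessError(PhenoKGError, ValueError):
    """An already-superseded named graph was targeted by a revision."""


class UnresolvableComparativeError(PhenoKGError, ValueError):
    """A comparative statement lacks the reference value needed to ground it.

    Comparative descriptions ("increased length of abdomen") only carry
    information relative to some reference condition; without the reference
    measurement the actual bound cannot be derived.
    """


class PreconditionError(PhenoKGError, ValueError):
    """An operation's stated precondition does not hold (e.g. nanopublication
    export for a graph with no provenance metadata)."""
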