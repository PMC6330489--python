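"""Exception hierarchy for goshare.

All library errors derive from :class:`GoshareError` so callers (and the
CLI) can distinguish bad input from internal failures with one except
clause.
"""


class GoshareError(Exception):
    """Base class for all goshare errors."""


class OboParseError(GoshareError):
    """A malformed OBO stanza or an unsatisfiable reference; names the line."""


class OntologyValidationError(GoshareError):
    """The parsed term graph violates a structural requirement (e.g. a cycle)."""


class UnknownTermError(GoshareError, LookupError):
    """A term identifier that is neither a primary id nor an alt_id."""

    def __init__(self, term_id: str):
        super().__init__(f"unknown GO term identifier: {term_id!r}")
        self.term_id = term_id


class ObsoleteTermError(GoshareError, LookupError):
    """A term identifier that resolves to an obsolete term."""

    def __init__(self, term_id: str):
        super().__init__(f"obsolete GO term: {term_id!r}")
        self.term_id = term_id


class GafParseError(GoshareError):
    """A malformed GAF line; the message carries the 1-based line number."""


class InputError(GoshareError):
    """User-supplied gene lists or configuration that cannot be processed."""


class ScoreDomainError(GoshareError, ValueError):
    """Background count below the minimum for which p(t) <= 1."""


class FixtureError(GoshareError):
    """Infeasible synthetic-fixture parameters."""
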