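"""Exception hierarchy.

Everything raised on purpose derives from :class:`ProteoflowError` so callers
can catch the library's own failures separately from programming errors.
"""


class ProteoflowError(Exception):
    """Base class for all errors raised by proteoflow."""


class FormatError(ProteoflowError):
    """A file could not be parsed; the message names the offending line."""


class DimensionError(ProteoflowError):
    """Input has the wrong shape (e.g. fewer than two sample columns)."""


class ValidationError(ProteoflowError):
    """Content violates a structural rule (self-loop, cycle, bad digest...)."""


class ParameterError(ProteoflowError):
    """A user-supplied parameter is outside its admissible range."""


class DesignError(ProteoflowError):
    """The sample design is inconsistent with the requested analysis."""


class CoverageError(ProteoflowError):
    """The mapping table does not cover a requested namespace pair."""


class EmptyDatabaseError(ProteoflowError):
    """No database records survive filtering (e.g. wrong species)."""


class DegenerateVarianceError(ProteoflowError):
    """All residual variances are zero; moderation is undefined."""


class TokenError(ProteoflowError):
    """A session token is corrupt, truncated or not decodable."""


class SchemaVersionError(TokenError):
    """A session token was produced under an unknown schema version."""
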