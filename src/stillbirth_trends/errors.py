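"""Exception hierarchy for the package.

All errors derive from :class:`StillbirthTrendsError` so callers can catch
pipeline failures with a single except clause while tests discriminate on
the concrete class.
"""


class StillbirthTrendsError(Exception):
    """Base class for all package errors."""


class SchemaError(StillbirthTrendsError):
    """Input file does not match the expected column schema."""


class ValidationError(StillbirthTrendsError):
    """Table content violates an invariant (negative counts, duplicate keys...)."""


class UnresolvableMissingnessError(StillbirthTrendsError):
    """An 'unknown' stratum carries counts but no known stratum can absorb them."""


class ConfigurationError(StillbirthTrendsError):
    """Invalid or incomplete configuration (missing disclosure bound, bad shares...)."""


class LookupError_(StillbirthTrendsError):
    """Requested country / year / axis not present in the table."""


class InsufficientDataError(StillbirthTrendsError):
    """Series too short for the requested statistical procedure."""


class UndefinedRateError(StillbirthTrendsError):
    """Rate requested for a population with zero total births."""
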