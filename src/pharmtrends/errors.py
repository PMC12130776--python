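"""Exception hierarchy.

All errors raised by this package derive from :class:`PharmTrendsError`
so callers can catch everything from one base class; the CLI maps any
of these to a non-zero exit with the message on stderr.
"""


class PharmTrendsError(Exception):
    """Base class for all package errors."""


class AtcParseError(PharmTrendsError, ValueError):
    """An ATC code string violates the WHO syntax rules."""


class SchemaError(PharmTrendsError):
    """An input file is missing mapped columns or has an unusable layout."""


class RowParseError(PharmTrendsError):
    """A cell in an input table could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DataValidationError(PharmTrendsError, ValueError):
    """Parsed data violates a domain invariant (negative count, bad range...)."""
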