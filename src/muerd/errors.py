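"""Exception hierarchy.

Every error raised by this package derives from :class:`MuErdError`, so callers
can catch one type at the pipeline boundary.  The CLI maps subclasses onto exit
codes (2 validation, 3 I/O, 4 degenerate data).
"""


class MuErdError(Exception):
    """Base class for all muerd errors."""


class FormatError(MuErdError, ValueError):
    """A file could not be parsed under the declared format."""


class LayoutError(MuErdError, ValueError):
    """Channel layout is inconsistent or missing a required role."""


class ParameterError(MuErdError, ValueError):
    """An analysis parameter is out of its valid range."""


class SpecificationError(MuErdError, ValueError):
    """A synthetic-data specification is incomplete or invalid."""


class DesignError(MuErdError, ValueError):
    """The statistical design is unbalanced or has missing cells."""


class PairingError(MuErdError, ValueError):
    """Numerator and denominator of an ERD ratio are not a valid pair."""


class DegenerateDataError(MuErdError, ValueError):
    """An operation received data on which its result is undefined."""


class IOFailure(MuErdError, OSError):
    """Reading or writing a file failed for non-format reasons."""
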