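"""Exception hierarchy.

Everything derives from :class:`ThzPelletError` so callers can catch the
package's failures with one clause; the leaves also subclass the closest
builtin (ValueError / OSError / KeyError) so generic handling keeps working.
"""


class ThzPelletError(Exception):
    """Base class for all errors raised by thzpellet."""


class FormatError(ThzPelletError, ValueError):
    """A delimited-text file does not parse as the expected layout."""


class SchemaError(ThzPelletError, ValueError):
    """A table is missing a required column."""


class ValidationError(ThzPelletError, ValueError):
    """A value violates a domain invariant (non-positive mass, bad grid, ...)."""


class DomainError(ThzPelletError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(ThzPelletError, ValueError):
    """A simulation/extraction configuration is unusable (grid too coarse, ...)."""


class DetectionError(ThzPelletError, ValueError):
    """A required signal feature (e.g. an etalon echo) could not be found."""


class FitError(ThzPelletError, ValueError):
    """A least-squares fit has too few points or is otherwise degenerate."""


class LookupError_(ThzPelletError, KeyError):
    """A named record (e.g. a biochemistry analyte) is absent from a table."""
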