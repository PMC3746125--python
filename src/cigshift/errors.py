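"""Exception hierarchy shared across the package."""


class CigshiftError(Exception):
    """Base class for all package errors."""


class DomainError(CigshiftError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ValidationError(CigshiftError, ValueError):
    """Structured input (CSV panel, schedule, config) failed validation."""


class GenerationError(CigshiftError, RuntimeError):
    """The synthetic-market generator produced an inadmissible state
    (e.g. a non-positive price); names the offending brand and period."""


class MissingDataError(CigshiftError, LookupError):
    """A requested period / segment / brand has no data.

    Raised instead of silently returning zero: a segment that does not exist
    in a period (e.g. the ultra-low-price tier before its market entry) is a
    gap, not a zero price.
    """
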