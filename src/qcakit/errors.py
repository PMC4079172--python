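"""Exception hierarchy for qcakit.

All package errors derive from :class:`QcaError` so callers can catch the
library's failures with a single except clause while still distinguishing
schema problems from data problems or set-algebra parse errors.
"""


class QcaError(Exception):
    """Base class for all qcakit errors."""


class SchemaError(QcaError):
    """A declared column or condition is missing or ill-formed."""


class DataValidationError(QcaError):
    """A cell value violates a membership invariant (range, crispness, domain)."""


class LabelParseError(QcaError):
    """A configuration label could not be parsed.

    Carries ``position``, the character offset of the offending token in the
    input text (best effort).
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class MembershipAssignmentError(QcaError):
    """A fuzzy membership of exactly 0.5 cannot be assigned to a truth-table corner."""


class UndefinedMetricError(QcaError):
    """A consistency or coverage denominator is zero."""


class NoSolutionError(QcaError):
    """No configuration passed the consistency cutoff; nothing to minimise."""
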