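"""Exception hierarchy for alsprog.

All package errors derive from :class:`AlsprogError` so callers can catch
one base class at pipeline boundaries (the CLI does exactly that).
"""


class AlsprogError(Exception):
    """Base class for all alsprog errors."""


class ValidationError(AlsprogError, ValueError):
    """An input value violates a domain invariant (score range, time sign...)."""


class DomainError(AlsprogError, ValueError):
    """A mathematically out-of-domain request (e.g. inverting the curve at y >= Ymax)."""


class MissingItemError(ValidationError):
    """A 12-item ALSFRS-R record has a missing sub-score."""


class ConflictError(ValidationError):
    """A row carries both a total score and item scores that disagree."""


class DuplicateVisitError(ValidationError):
    """Two visits of the same patient share a timestamp."""


class FormatError(AlsprogError, ValueError):
    """An input file row could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class ZeroSlopeError(AlsprogError, ValueError):
    """The conventional slope is zero or negative, so no decline-based
    initialization exists; carries the flat-trajectory flag."""

    def __init__(self, slope: float):
        super().__init__(
            f"conventional slope {slope:g} is not a positive decline rate; "
            "cannot initialize the logistic fit"
        )
        self.slope = slope


class EligibilityError(AlsprogError, ValueError):
    """Trajectory does not meet the >= 3 observations fitting requirement."""
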