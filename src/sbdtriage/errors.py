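"""Exception hierarchy for the triage pipeline.

Every error raised by the package derives from :class:`SbdTriageError`, so
callers (and the CLI) can catch one base class.
"""


class SbdTriageError(Exception):
    """Base class for all package errors."""


class MissingDataError(SbdTriageError):
    """A computation needed a value that is absent.

    Raised instead of silently treating a missing histology flag or marker as
    "normal"; missingness is always surfaced, never imputed.
    """


class CohortParseError(SbdTriageError):
    """A cohort CSV row could not be parsed; the message names the row."""


class UndefinedOddsRatioError(SbdTriageError):
    """A 2x2 table has an all-zero margin, so no odds ratio exists."""


class SeparationError(SbdTriageError):
    """A regression predictor perfectly separates the outcome."""


class ConvergenceError(SbdTriageError):
    """An iterative fit failed to converge within its iteration budget."""
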