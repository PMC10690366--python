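"""Exception hierarchy for the hipscore pipeline.

Every stage raises a subclass of :class:`HipscoreError`, so callers (and the
CLI) can catch one type and report the offending stage/input.
"""


class HipscoreError(Exception):
    """Base class for all hipscore errors."""


class ConfigurationError(HipscoreError):
    """Invalid configuration (empty cohort, negative SD, bad split sizes...)."""


class ValidationError(HipscoreError):
    """A data table violates its schema or the rubric's constraints."""


class DegenerateDataError(HipscoreError):
    """The data carry no usable information for the requested computation.

    Raised e.g. when every column of a score matrix is constant, so the
    entropy weight method has zero total diversity to distribute.
    """


class UndefinedStatisticError(HipscoreError):
    """A statistic is undefined on this input (zero variance, constant vector)."""


class DivergenceError(HipscoreError):
    """Model training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")
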