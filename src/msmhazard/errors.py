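"""Exception hierarchy for msmhazard.

Every error raised by the library derives from :class:`MSMHazardError` so that
callers (and the CLI) can catch library failures without masking bugs.
"""


class MSMHazardError(Exception):
    """Base class for all msmhazard errors."""


class SchemaError(MSMHazardError):
    """A required column is missing or mis-typed in an input table."""


class PanelValidationError(MSMHazardError):
    """A person-visit panel violates a structural invariant."""


class ConfigError(MSMHazardError):
    """An invalid pipeline or generator configuration."""


class EstimationError(MSMHazardError):
    """Base class for model-fitting failures."""


class RankDeficiencyError(EstimationError):
    """The design matrix is rank deficient; carries the offending columns."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class SeparationError(EstimationError):
    """Detected (quasi-)complete separation / monotone likelihood."""


class ConvergenceError(EstimationError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None, iterations=None):
        super().__init__(message)
        self.last_params = last_params
        self.iterations = iterations


class ZeroEventsError(EstimationError):
    """No events in the analysis (sub)sample, so no hazard is estimable."""


class InfiniteWeightError(MSMHazardError):
    """A propensity prediction of exactly 0 or 1 would yield an infinite weight."""
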