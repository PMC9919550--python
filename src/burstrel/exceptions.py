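"""Exception hierarchy for burstrel."""


class BurstrelError(Exception):
    """Base class for all burstrel errors."""


class SchemaError(BurstrelError):
    """A required column is missing or a file does not match the documented schema."""


class RowValidationError(BurstrelError):
    """One or more rows violate a dataset invariant; message carries row-level diagnostics."""


class DuplicateKeyError(BurstrelError):
    """Duplicate (person, session, task, trial) key in a burst dataset."""


class DesignError(BurstrelError):
    """The measurement design is too degenerate for the requested analysis."""


class DegenerateScaleError(BurstrelError):
    """A task has zero score variance in the standardization pool."""


class UndefinedReliabilityError(BurstrelError):
    """A reliability coefficient has a zero denominator."""


class ConvergenceError(BurstrelError):
    """The iterative variance-component estimator failed to converge."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class ConfigError(BurstrelError):
    """Invalid simulation or pipeline configuration."""


class PipelineError(BurstrelError):
    """A pipeline stage failed; message names the stage."""
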