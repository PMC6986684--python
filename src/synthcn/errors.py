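"""Exception hierarchy shared across the pipeline stages."""


class SynthCnError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SynthCnError, ValueError):
    """An input value violates a precondition (non-positive size, empty region, ...)."""


class FrameError(InvalidInputError):
    """Aligned coding sequences are incompatible with codon-wise comparison."""


class SaturationError(SynthCnError, ValueError):
    """A distance correction is undefined because divergence is at or past saturation."""


class DegenerateInputError(SynthCnError, ValueError):
    """A statistic is undefined because the data carry no variance."""


class ConfigurationError(SynthCnError):
    """A run configuration is incomplete or inconsistent (missing sample metadata, paths...)."""


class ConditioningError(SynthCnError):
    """A covariance matrix is numerically singular beyond repair."""


class InsufficientDataError(SynthCnError):
    """Too few matched observations remain after joining data sources."""


class StageFailure(SynthCnError):
    """A pipeline stage failed; carries the stage name for the run log."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
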