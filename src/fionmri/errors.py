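"""Exception hierarchy shared across the pipeline stages."""


class FionMRIError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FionMRIError, ValueError):
    """A simulation or run configuration is internally inconsistent."""


class ValidationError(FionMRIError, ValueError):
    """Input data violates a structural contract (NaNs, non-binary mask, ...)."""


class GridMismatchError(FionMRIError, ValueError):
    """Volumes or masks do not share one voxel grid."""


class EmptyROIError(FionMRIError, ValueError):
    """An operation requires a non-empty region of interest."""


class DegenerateReferenceError(FionMRIError, ValueError):
    """The muscle reference signal is zero or negative; normalization undefined."""


class SampleSizeError(FionMRIError, ValueError):
    """A statistical test was asked to run on too few observations."""


class PipelineStageError(FionMRIError, RuntimeError):
    """Wraps a failure inside a named stage of the lesion pipeline."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
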