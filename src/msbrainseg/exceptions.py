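"""Exception hierarchy shared across the pipeline."""


class MSBrainSegError(Exception):
    """Base class for all package errors."""


class ValidationError(MSBrainSegError):
    """A record, fold file or configuration violates an invariant."""


class FormatError(MSBrainSegError):
    """A container file is missing an expected field or has an unknown layout."""


class GenerationError(MSBrainSegError):
    """A phantom could not be generated under the requested geometry."""


class AugmentationError(MSBrainSegError):
    """An elastic deformation produced an unusable record (e.g. empty mask)."""


class SamplingError(MSBrainSegError):
    """Not enough eligible window centers of the requested class."""


class StatisticsError(MSBrainSegError):
    """Degenerate normalization statistics (zero pooled variance)."""


class ConfigurationError(MSBrainSegError):
    """A network configuration is internally inconsistent."""


class TrainingError(MSBrainSegError):
    """Training diverged (non-finite loss) or was misconfigured."""
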