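"""Exception hierarchy shared across the pipeline stages."""

__all__ = [
    "DropgrowthError",
    "ConfigurationError",
    "FormatError",
    "GenerationError",
    "MeasurementError",
    "InsufficientDataError",
    "ThresholdUndefinedError",
    "NormalizationError",
    "StageError",
]


class DropgrowthError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DropgrowthError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class FormatError(DropgrowthError):
    """Unreadable or unsupported input image format (CLI exit code 3)."""


class GenerationError(DropgrowthError):
    """Synthetic scene could not be generated (placement/bounds failure)."""


class MeasurementError(DropgrowthError):
    """Per-droplet measurement on a degenerate ROI or mask."""


class InsufficientDataError(DropgrowthError):
    """Too few observations for the requested statistic."""


class ThresholdUndefinedError(DropgrowthError):
    """No strictly positive day-0 growth values; supply a floor threshold."""


class NormalizationError(DropgrowthError):
    """Normalization scope lacks a positive maximum."""


class StageError(DropgrowthError):
    """A pipeline stage failed (CLI exit code 4)."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        self.detail = detail
        super().__init__(f"stage '{stage}' failed: {detail}")
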