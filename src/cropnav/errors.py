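"""Exception types shared across the package."""


class CropNavError(Exception):
    """Base class for all package errors."""


class ParameterError(CropNavError, ValueError):
    """An invalid configuration or operation parameter; names the offending field."""


class ShapeError(CropNavError, ValueError):
    """Array shapes incompatible with the requested operation."""


class ValidationError(CropNavError, ValueError):
    """Input data violates a documented precondition (e.g. non-binary mask)."""


class DatasetError(CropNavError, ValueError):
    """A dataset directory is missing, empty or malformed."""


class FitError(CropNavError, RuntimeError):
    """Line fitting cannot proceed (too few points, degenerate geometry)."""


class SamplingExhausted(CropNavError, RuntimeError):
    """No candidate pair satisfied the separation constraint within the retry budget."""


class TrainingError(CropNavError, RuntimeError):
    """Training diverged; carries the epoch at which the loss became non-finite."""


class CheckpointError(CropNavError, RuntimeError):
    """Checkpoint missing or incompatible with the requested architecture."""
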