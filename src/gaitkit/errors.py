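"""Exception hierarchy shared across the pipeline stages."""


class GaitKitError(Exception):
    """Base class for all gaitkit errors."""


class ParseError(GaitKitError):
    """A keypoint or event file could not be parsed; message names the line."""


class ValidationError(GaitKitError):
    """An input violated a documented invariant (range, ordering, shape)."""


class InsufficientDataError(GaitKitError):
    """Too few valid samples/events for the requested computation."""


class AmbiguousDirectionError(GaitKitError):
    """Walking direction could not be inferred; supply it in the config."""


class BackendUnavailableError(GaitKitError):
    """No pose-estimation backend is installed or was provided."""


class DegenerateDataError(GaitKitError):
    """A statistic is undefined for this input (zero variance, constant)."""


class StageError(GaitKitError):
    """Wraps an error raised inside a pipeline stage with context."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for subject '{subject_id}': {cause}")
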