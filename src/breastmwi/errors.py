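"""Exception hierarchy shared across the pipeline stages."""


class BreastMWIError(Exception):
    """Base class for all package errors."""


class ValidationError(BreastMWIError, ValueError):
    """An input violates a documented precondition or invariant."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but carries no usable signal (empty mask, constant volume, ...)."""


class DimensionalityError(ValidationError):
    """A volume does not have exactly three spatial dimensions."""


class GridMismatchError(ValidationError):
    """Two volumes expected on the same grid differ in shape or spacing."""


class TransformError(BreastMWIError):
    """A spatial transform is singular or otherwise unusable."""


class RegistrationError(BreastMWIError):
    """Image registration failed to converge; carries the final metric value."""

    def __init__(self, message: str, metric_value: float | None = None):
        super().__init__(message)
        self.metric_value = metric_value


class SeedError(ValidationError):
    """A region-growing seed lies outside the admissible intensity window."""


class SternumNotFoundError(BreastMWIError):
    """No voxel above the mean intensity along the midline column."""


class FitError(BreastMWIError):
    """A model fit (GMM, Debye) failed; may carry a residual report."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class StageError(BreastMWIError):
    """A pipeline stage failed; wraps the underlying error with stage context."""

    def __init__(self, stage: str, params: dict, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.params = params
        self.cause = cause
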