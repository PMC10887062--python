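"""Exception types shared across isdkit modules."""


class ISDKitError(Exception):
    """Base class for all isdkit errors."""


class SchemaError(ISDKitError):
    """A covariate schema is inconsistent with the data it is applied to."""


class ValidationError(ISDKitError):
    """A record or table failed validation."""


class ConvergenceError(ISDKitError):
    """An iterative fit did not reach its convergence tolerance."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm
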