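"""Exception types shared across the package."""


class CcnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CcnetError, ValueError):
    """A cohort or model specification violates its invariants."""


class DataError(CcnetError, ValueError):
    """Input data violate a structural contract (shape, sign, missingness)."""


class InvalidParameterError(CcnetError, ValueError):
    """A function argument is outside its documented range."""


class EstimationError(CcnetError, RuntimeError):
    """A model could not be estimated from the data provided."""
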