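"""Exception hierarchy shared across the package."""


class ChromvalError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ChromvalError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDesignError(ChromvalError, ValueError):
    """A calibration or study design carries no usable information
    (e.g. a single distinct concentration level)."""


class InvalidFitError(ChromvalError, ValueError):
    """A fitted calibration cannot support the requested derived quantity
    (e.g. LOD from a non-positive slope)."""


class InsufficientBaselineError(ChromvalError, ValueError):
    """Too few baseline QC points to estimate control-chart limits."""


class DegenerateBaselineError(ChromvalError, ValueError):
    """QC baseline has zero spread; chart limits would collapse."""
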