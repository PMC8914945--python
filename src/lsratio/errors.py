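"""Exception hierarchy shared across the package."""


class LSRatioError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LSRatioError, ValueError):
    """A parameter violates its contract (sign, range, shape)."""


class ConfigurationError(LSRatioError, ValueError):
    """A configuration object is internally inconsistent."""


class EmptyRangeError(LSRatioError, ValueError):
    """A requested spectral window contains no grid points."""


class InvalidGridError(LSRatioError, ValueError):
    """The wavenumber grid does not satisfy a required property."""


class DegenerateInputError(LSRatioError, ValueError):
    """Input data carry no usable variance."""


class ConvergenceError(LSRatioError, RuntimeError):
    """An iterative fit failed to converge."""


class FormatError(LSRatioError, ValueError):
    """A file does not conform to its declared format."""


class UndefinedMetricError(LSRatioError, ValueError):
    """A requested metric is undefined for the given data."""


class CannotSplitError(LSRatioError, ValueError):
    """The dataset cannot be partitioned as requested."""
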