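"""Exception hierarchy shared across the package."""


class MRSIKitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MRSIKitError, ValueError):
    """A physical parameter is outside its admissible range."""


class ConfigurationError(MRSIKitError, ValueError):
    """A processing option or configuration value is inconsistent."""


class DataError(MRSIKitError, ValueError):
    """Input data are malformed (non-finite samples, shape mismatch ...)."""


class IdentifiabilityError(MRSIKitError, ValueError):
    """The model is not locally identifiable (singular Fisher matrix)."""


class OverparameterizationError(MRSIKitError, ValueError):
    """Too many free parameters for the number of data points."""


class EmptyModelError(MRSIKitError, ValueError):
    """No spectral peak could be detected to initialize a model."""
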