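"""Exception hierarchy shared across the pipeline stages."""


class IcdmirError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IcdmirError):
    """A file does not conform to its declared dialect."""


class ConsistencyError(IcdmirError):
    """Two inputs that must agree (ids, dimensions) do not."""


class ParameterError(IcdmirError):
    """A parameter is outside its documented range."""


class ConfigurationError(IcdmirError):
    """A configuration is internally contradictory or infeasible."""


class ContrastError(IcdmirError):
    """A requested contrast group is missing or unknown."""


class NormalizationError(IcdmirError):
    """Size-factor estimation is impossible for the given matrix."""


class SequenceError(IcdmirError):
    """A sequence contains characters outside its alphabet."""
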