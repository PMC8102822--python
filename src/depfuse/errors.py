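"""Exception hierarchy shared across the package."""


class DepfuseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DepfuseError, ValueError):
    """Invalid model or training configuration (bad sizes, non-positive rates...)."""


class DimensionMismatchError(DepfuseError, ValueError):
    """Array arguments whose shapes do not match the model parameters."""


class InvalidInputError(DepfuseError, ValueError):
    """Structurally invalid data (empty minibatch, probability outside (0,1)...)."""


class DegenerateFrameError(InvalidInputError):
    """A frame whose coordinate set is constant and cannot be standardized."""


class SessionFormatError(DepfuseError, ValueError):
    """On-disk session layout violates the documented format."""
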