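"""Exception hierarchy shared across the package."""


class HepsimError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HepsimError):
    """A file is missing required metadata, layers, or columns."""


class GridMismatchError(HepsimError):
    """Two gridded layers do not share the same grid."""


class ParameterError(HepsimError, ValueError):
    """A model parameter violates its admissible range."""


class StabilityError(HepsimError):
    """A time step violates a numerical stability bound."""


class ConfigError(HepsimError):
    """A scenario/CLI configuration is invalid or incomplete."""
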