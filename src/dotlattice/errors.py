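"""Exception hierarchy for the dotlattice package."""


class DotLatticeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DotLatticeError, ValueError):
    """A model parameter is outside its admissible range."""


class InvalidDensityError(DotLatticeError, ValueError):
    """A density array is not a valid probability density on its grid."""


class InvalidConditionError(DotLatticeError, ValueError):
    """A trial condition is malformed (bad aspect ratio, missing percept, ...)."""


class ConfigurationError(DotLatticeError, ValueError):
    """A configuration value (grid step, prior kind, config key) is invalid."""


class AnalysisError(DotLatticeError, ValueError):
    """An effect-estimation step received unusable input."""
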