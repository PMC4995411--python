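"""Exception hierarchy shared across the package."""


class CanolodgeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CanolodgeError, ValueError):
    """An argument is outside its physical or mathematical domain."""


class DegenerateInputError(CanolodgeError, ValueError):
    """An input is formally valid but makes the requested quantity undefined
    (e.g. a zero self-weight moment in a safety-factor ratio)."""


class FitDegenerateError(CanolodgeError, ValueError):
    """A regression cannot be fitted (constant predictor, too few points)."""


class ConfigError(CanolodgeError, ValueError):
    """A run or trial configuration is inconsistent or refers to unknown names."""
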