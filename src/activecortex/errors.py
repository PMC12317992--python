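"""Exception hierarchy shared across the package."""


class ActiveCortexError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ActiveCortexError):
    """A file could not be parsed (names the offending row/column)."""


class SchemaError(ActiveCortexError):
    """Inputs are structurally inconsistent (shape/label mismatches)."""


class ConfigurationError(ActiveCortexError):
    """An option value is outside its supported range."""


class ValidationError(ActiveCortexError):
    """Data fail a precondition of the requested analysis."""


class StatisticalValidityError(ValidationError):
    """Too few observations for the statistic to be meaningful."""


class NumericalError(ActiveCortexError):
    """A linear-algebra step failed; the message carries a remedy hint."""


class StabilityError(ActiveCortexError):
    """A simulated trajectory diverged."""
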