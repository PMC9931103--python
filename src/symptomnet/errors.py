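"""Exception hierarchy for symptomnet."""


class SymptomnetError(Exception):
    """Base class for all package errors."""


class ConfigError(SymptomnetError):
    """A configuration value is invalid or inconsistent."""


class FormatError(SymptomnetError):
    """An input file does not match the expected layout."""


class ValidationError(SymptomnetError):
    """Data violates a declared constraint (e.g. a score out of range)."""


class EstimationError(SymptomnetError):
    """A statistical estimate cannot be computed from the data given."""
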