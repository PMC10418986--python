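"""Package-level exception types."""


class PriovarError(Exception):
    """Base class for all package errors."""


class ParseError(PriovarError):
    """Malformed input file; the message names the offending line/record."""


class ConfigurationError(PriovarError):
    """Cohort/sample/threshold configuration is inconsistent with the data."""


class InputError(PriovarError):
    """A computation received arguments outside its domain."""
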