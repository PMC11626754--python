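"""Exception hierarchy."""


class ClimtaxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClimtaxError):
    """Invalid configuration (non-conformable matrices, bad probabilities...)."""


class FormatError(ClimtaxError):
    """Structurally broken input file (missing columns, unparseable)."""


class ValidationError(ClimtaxError):
    """Input parses but violates a dataset invariant (duplicates, bad keys)."""
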