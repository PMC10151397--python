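"""Structured error types raised across the pipeline."""


class CrypteqtlError(Exception):
    """Base class for all package errors."""


class ParseError(CrypteqtlError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(CrypteqtlError):
    """Parsed data violates an invariant (dimensions, labels, duplicates)."""


class ParameterError(CrypteqtlError):
    """A function argument is outside its allowed range."""
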