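"""Exception hierarchy for germeval."""


class GermevalError(Exception):
    """Base class for all germeval errors."""


class ValidationError(GermevalError):
    """Raised when an input table, config, or matrix fails validation."""


class DegenerateDataError(GermevalError):
    """Raised when data are too degenerate for an operation (constant
    column, singleton group, zero score range, ...)."""
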