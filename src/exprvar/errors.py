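"""Exception types shared across the package."""


class ExprvarError(Exception):
    """Base class for all package errors."""


class ValidationError(ExprvarError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(ExprvarError, ValueError):
    """A text file could not be parsed; the message names the location."""
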