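"""Exception hierarchy shared across the package."""


class MethExprError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MethExprError):
    """A file could not be parsed (malformed header, ragged row, duplicate ID...)."""


class ValidationError(MethExprError):
    """Parsed content violates a domain invariant (unknown level, bad config...)."""
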