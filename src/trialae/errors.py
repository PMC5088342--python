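"""Exception types shared across the package."""


class TrialAEError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TrialAEError):
    """Raised when an input document cannot be parsed at all."""


class ValidationError(TrialAEError):
    """Raised when parsed or constructed data violates a record invariant.

    The message always names the offending record (trial/arm id) and field.
    """
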