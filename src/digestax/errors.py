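"""Exception types shared across the package."""


class DigestaxError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DigestaxError, ValueError):
    """Raised when user-supplied data violates a documented precondition."""
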