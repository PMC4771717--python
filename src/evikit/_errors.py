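"""Exception types shared across the package."""


class EvikitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EvikitError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(EvikitError, ValueError):
    """A file cannot be parsed as the expected external format."""
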