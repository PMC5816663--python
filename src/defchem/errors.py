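"""Exception hierarchy."""


class DefchemError(Exception):
    """Base class for all package errors."""


class TreeFormatError(DefchemError):
    """A tree file could not be parsed in the declared dialect."""


class ValidationError(DefchemError):
    """Structurally parseable input that violates a domain invariant."""


class FitError(DefchemError):
    """A likelihood computation or optimization produced an unusable result."""
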