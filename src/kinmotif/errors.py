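"""Exception hierarchy. CLI maps ValidationError -> exit 1, OSError -> exit 2."""


class KinmotifError(Exception):
    """Base class for all package errors."""


class ValidationError(KinmotifError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A tabular artifact does not match the expected layout."""
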