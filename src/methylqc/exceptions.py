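"""Exception hierarchy shared across the package."""


class MethylQcError(Exception):
    """Base class for all package errors."""


class FormatError(MethylQcError):
    """A file does not conform to its documented format."""


class ValidationError(MethylQcError):
    """Data violates a structural invariant (duplicate ids, shape mismatch, ...)."""


class ConfigurationError(MethylQcError):
    """A user-supplied policy or configuration is inconsistent."""


class FitError(MethylQcError):
    """A model fit failed irrecoverably."""
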