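"""Exception hierarchy shared across the toolkit.

Validation-type failures (bad parameters, malformed annotation files,
degenerate geometry) are distinguished from I/O-type failures so the CLI
can map them to distinct exit codes (2 and 3 respectively).
"""


class VBBError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(VBBError):
    """Input violates a documented invariant (bad landmark file, duplicate id...)."""


class ParameterError(ValidationError):
    """A function argument is out of its documented range."""


class PreconditionError(ValidationError):
    """A documented precondition of an operation does not hold."""


class DegenerateOutputError(VBBError):
    """An operation would produce an empty or meaningless result."""


class DegeneracyError(VBBError):
    """Geometric configuration is degenerate (e.g. collinear landmarks)."""


class ConfigurationError(VBBError):
    """A workflow/registration configuration is unusable."""


class FormatError(VBBError):
    """A file is not in a recognized/parseable format."""


class AmbiguityWarning(UserWarning):
    """Raised (as a warning) when an initialization is not uniquely determined."""


class EmptyResultWarning(UserWarning):
    """Raised (as a warning) when a query legitimately returns nothing."""
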