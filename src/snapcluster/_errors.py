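"""Exception hierarchy shared across the package."""


class SnapclusterError(Exception):
    """Base class for all package errors."""


class ValidationError(SnapclusterError):
    """Invalid inputs, shapes, names or parameter values."""


class UsageError(SnapclusterError):
    """A precondition on how an operation is called was violated."""


class TrainingError(SnapclusterError):
    """Optimization failed (e.g. non-finite loss)."""
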