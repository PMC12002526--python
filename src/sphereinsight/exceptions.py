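"""Exception hierarchy shared across the package."""


class SphereInsightError(Exception):
    """Base class for all package errors."""


class ValidationError(SphereInsightError):
    """An input violates a documented invariant (negative count, bad shape...)."""


class FormatError(SphereInsightError):
    """An on-disk file is malformed; the message names the offending cell/row."""


class ConvergenceError(SphereInsightError):
    """An iterative solver failed to converge within its budget."""

    def __init__(self, message, last_iterate=None, step_norm=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.step_norm = step_norm


class DomainError(SphereInsightError):
    """A mathematically valid value lies outside the map's domain (e.g. antipode)."""
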