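"""Exception hierarchy."""


class PimsflowError(Exception):
    """Base class for package errors."""


class InvalidInputError(PimsflowError, ValueError):
    """An argument violates a documented precondition."""


class EmptySpectrumError(PimsflowError):
    """No charge-assigned ions are available to build a spectrum."""


class InfeasibleConfigurationError(PimsflowError):
    """The bin/target configuration cannot satisfy the allocation mode."""


class NonConvergenceError(PimsflowError):
    """Bin allocation hit the iteration cap; carries the partial result."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class MissingWindowError(PimsflowError):
    """An assigned target has no isolation window."""


class InsufficientAnchorsError(PimsflowError):
    """Fewer than two calibration anchors were supplied."""


class DegenerateVarianceError(PimsflowError):
    """The count matrix has no variance to decompose."""
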