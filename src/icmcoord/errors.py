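"""Exception types shared across the package."""


class IcmcoordError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IcmcoordError, ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


class FormatError(IcmcoordError, ValueError):
    """Raised when a delimited-text input cannot be parsed.

    The message names the offending row and/or column so the file can
    be fixed by hand.
    """


class InputError(IcmcoordError, ValueError):
    """Raised when an operation receives data it cannot work with
    (missing gene, too few cells, inconsistent ids...)."""


class ConvergenceError(IcmcoordError, RuntimeError):
    """Raised when an iterative fit does not converge.

    Carries the per-iteration objective trace in ``history``.
    """

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []
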