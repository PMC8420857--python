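"""Exception hierarchy.

All package-specific failures derive from :class:`CD2StructError` so callers
can catch one base class; subclasses also derive from the matching builtin
(``ValueError`` / ``RuntimeError``) to behave well in generic code.
"""


class CD2StructError(Exception):
    """Base class for all cd2struct errors."""


class InvalidParameterError(CD2StructError, ValueError):
    """A numeric parameter violated its precondition (e.g. non-positive path length)."""


class OutOfRangeError(CD2StructError, ValueError):
    """A requested wavelength grid or interval lies outside the available data."""


class ConsistencyError(CD2StructError, ValueError):
    """Two inputs that must agree (grids, sequences, lengths) do not."""


class InvalidSequenceError(CD2StructError, ValueError):
    """A sequence contains characters outside the supported alphabet."""


class NoSolutionError(CD2StructError, RuntimeError):
    """Deconvolution retained no solution after the selection rules.

    Carries the diagnostics object so callers can inspect per-rule rejections.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class NonConvergenceError(CD2StructError, RuntimeError):
    """Self-consistent iteration failed to converge within ``max_iter``."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
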