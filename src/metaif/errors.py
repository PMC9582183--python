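"""Exception hierarchy shared across the package."""


class MetaifError(Exception):
    """Base class for all package-specific errors."""


class GridError(MetaifError):
    """Invalid or mismatched time/support grid."""


class DomainError(MetaifError, ValueError):
    """Input outside the mathematical domain of an operation."""


class DegenerateDataError(MetaifError, ValueError):
    """Sample has no usable variation (e.g. all values equal)."""


class ConvergenceError(MetaifError, RuntimeError):
    """Iterative solver failed to reach its tolerance.

    Carries the final residual (solver-specific meaning) in ``residual``.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class ConfigurationError(MetaifError, ValueError):
    """Invalid solver or pipeline configuration."""


class UnsupportedFamilyError(MetaifError, ValueError):
    """Basis pattern does not correspond to a known parametric family."""
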