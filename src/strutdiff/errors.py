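"""Exception hierarchy for strutdiff.

All errors derive from :class:`StrutdiffError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
because they signal invalid inputs.
"""


class StrutdiffError(Exception):
    """Base class for all strutdiff errors."""


class InvalidBleachError(StrutdiffError, ValueError):
    """Pre-bleach intensity does not exceed the first post-bleach intensity."""


class MalformedInputError(StrutdiffError, ValueError):
    """Structurally invalid trace or field (non-monotone times, shape mismatch)."""


class InsufficientRecoveryError(StrutdiffError, ValueError):
    """Recovery curve never reaches f = 0.5.

    Attributes
    ----------
    max_f : float
        The maximum fractional fluorescence observed, for diagnostics.
    """

    def __init__(self, msg: str, max_f: float):
        super().__init__(msg)
        self.max_f = max_f


class DomainError(StrutdiffError, ValueError):
    """A scalar argument is outside its physical domain (e.g. non-positive)."""


class UnphysicalRatioError(DomainError):
    """A diffusivity ratio D/D0 exceeds 1."""


class BadDiscretizationError(StrutdiffError, ValueError):
    """Simulation grid/time step violates a stability or resolution bound."""


class SpotExceedsLineError(StrutdiffError, ValueError):
    """Bleach spot does not fit inside the confining line pattern."""


class ResolutionMismatchError(StrutdiffError, ValueError):
    """A scaffold dimension is not an integer multiple of the voxel size."""

    def __init__(self, field: str, msg: str):
        super().__init__(msg)
        self.field = field


class NonConvergenceError(StrutdiffError, RuntimeError):
    """An iterative solve failed to converge.

    Attributes
    ----------
    residuals : list of float
        Residual history for diagnostics.
    """

    def __init__(self, msg: str, residuals=None):
        super().__init__(msg)
        self.residuals = list(residuals) if residuals is not None else []


class NotConvergedSeriesError(StrutdiffError, RuntimeError):
    """A simulation series never met the steady-state criterion."""
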