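"""Exception and warning types shared across the package."""


class KickoutError(ValueError):
    """Base class for all domain errors raised by this package."""


class ValidationError(KickoutError):
    """An input violates a documented invariant."""


class UndefinedOccupancyError(KickoutError):
    """Occupancy is 0/0: both the rebinding and the leaving rate are zero."""


class InconsistentInputsError(KickoutError):
    """Observed expression lies below the saturated floor r (or above 1)."""


class NoCrossingError(KickoutError):
    """Root bracketing failed: the target value is never crossed."""


class IllPosedPropagationError(KickoutError):
    """More than half of the Monte-Carlo draws violate model preconditions."""


class NormalizationError(KickoutError):
    """Control or blank levels make the requested normalization impossible."""


class NoGrowthError(KickoutError):
    """Growth-curve fit produced a non-positive growth rate."""


class FitFailureError(KickoutError):
    """Optimization failed to converge from every starting point."""


class DegenerateAxisWarning(UserWarning):
    """Vertex cloud is nearly isotropic; principal axis is ill-defined."""
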