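"""Exception hierarchy for kinematic degeneracies and contract violations."""


class ScrewAxisError(ValueError):
    """Base class for all screwaxis errors."""


class BranchCutError(ScrewAxisError):
    """Matrix logarithm requested for a rotation with angle at or beyond pi.

    The principal log of SO(3) is discontinuous at a half turn; rather than
    silently picking a branch the conversion refuses rotations with angle
    >= pi - 1e-6 rad between consecutive samples.
    """


class UndefinedAxisError(ScrewAxisError):
    """An axis direction or position cannot be determined from the data.

    Raised when all angular velocities are (numerically) zero, so neither the
    dominant eigendirection nor the pseudo-intersection point exists.
    """


class InsufficientDataError(ScrewAxisError):
    """Too few samples for the requested computation."""


class ValidationError(ScrewAxisError):
    """Input data violates a structural contract (bad rotation, bad sampling)."""
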