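"""Exception hierarchy.

All model-specific failures derive from :class:`WindkesselError` so callers
can distinguish them from programming errors; input-validation failures are
plain ``ValueError`` subclasses.
"""


class WindkesselError(Exception):
    """Base class for model-specific failures."""


class TimeDomainError(WindkesselError, ValueError):
    """Time argument outside the domain of the requested waveform branch."""


class DegenerateRootError(WindkesselError):
    """Characteristic polynomial has a repeated root (R^2 C^2 == 4 C I).

    The closed-form branches assume two distinct roots; the repeated-root
    case is measure-zero in the admissible parameter box and is handled by
    the numeric integrator only.
    """


class ModelInconsistencyError(WindkesselError):
    """Computed SBP <= DBP, signalling a coefficient-convention failure."""


class ConvergenceError(WindkesselError):
    """Numeric integration failed to reach a periodic steady state."""


class SurfaceBuildError(WindkesselError):
    """Forward pressure evaluation failed at a grid node."""


class UnreachablePressureError(WindkesselError):
    """Target blood pressure lies outside the surface range.

    Raised by contour extraction when the requested pressure is not attained
    anywhere in the admissible (R, C) box.
    """


class InsufficientDataError(WindkesselError, ValueError):
    """Too few distinct doses to fit a dose-effect curve."""


class FitError(WindkesselError):
    """Dose-effect least-squares fit failed to converge."""
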