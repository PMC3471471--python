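"""Cardiac integrated index (CII): weighted sum of 7 hemodynamic outputs.

CII = sum_i y_i * w_i over the profile (MAP, PP, HR, CO, SV, EF, SW), with
fixed weights derived from a principal-component analysis of model outputs.
The sum acts on raw values in their conventional units (mmHg, mmHg,
beats/min, L/min, mL, %, J/beat) — it is deliberately *not* standardized,
so the score is unit-convention dependent.  Lower CII indicates a better
overall cardiac state.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.integrate import quad

from .waveform import CardiacTiming, FlowWaveform, PressureTrace, input_flow

__all__ = ["HemodynamicProfile", "CIIWeights", "compute_cii", "profile_from_model"]

#: Fixed component order shared by profiles and weights.
COMPONENTS = ("map", "pp", "hr", "co", "sv", "ef", "sw")


@dataclass(frozen=True)
class HemodynamicProfile:
    """The 7-component hemodynamic vector scored by the CII.

    Units: MAP/PP mmHg, HR beats/min, CO L/min, SV mL, EF %, SW J/beat.
    """

    map: float  # mean arterial pressure
    pp: float   # pulse pressure
    hr: float
    co: float
    sv: float
    ef: float
    sw: float

    def __post_init__(self) -> None:
        if self.pp < 0:
            raise ValueError("pulse pressure must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


@dataclass(frozen=True)
class CIIWeights:
    """Weighting coefficients, in the fixed component order (dimensionless)."""

    map: float = 0.2333
    pp: float = 0.3084
    hr: float = 0.0415
    co: float = -0.3737
    sv: float = -0.3678
    ef: float = -0.3566
    sw: float = 0.3266

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def compute_cii(profile: HemodynamicProfile, weights: CIIWeights | None = None) -> float:
    """Dot product of the profile with the weights; lower is better.

    A missing (None or non-finite) component is an input error naming the
    offending component.
    """
    weights = weights or CIIWeights()
    for name in COMPONENTS:
        v = getattr(profile, name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"profile component {name.upper()!r} is missing or non-finite")
    return float(profile.as_array() @ weights.as_array())


def profile_from_model(
    trace: PressureTrace,
    wf: FlowWaveform | None = None,
    timing: CardiacTiming | None = None,
    supplements: dict | None = None,
) -> HemodynamicProfile:
    """Derive the profile components the single-segment model can supply.

    MAP is the time average of the trace, PP = SBP - DBP, HR = 60 /
    cycle_length (overridable via ``supplements["hr"]`` since a clinical HR
    measurement trumps the nominal cycle length), SV the inflow integral
    over one cycle (model flow units; see the methods note for the
    calibration caveat) and CO = SV * HR / 1000.  EF and SW cannot be
    produced by a one-segment vessel model and are mandatory supplements.
    """
    timing = timing or CardiacTiming()
    wf = wf or FlowWaveform(timing=timing)
    supplements = supplements or {}
    for needed in ("ef", "sw"):
        if needed not in supplements:
            raise ValueError(f"supplement {needed.upper()!r} is required")
    sv, _ = quad(
        lambda t: input_flow(t, wf),
        0.0,
        timing.cycle_length,
        points=[
            timing.systole_duration / 4,
            3 * timing.systole_duration / 4,
            timing.systole_duration,
        ],
        limit=200,
    )
    hr = supplements.get("hr", 60.0 / timing.cycle_length)
    return HemodynamicProfile(
        map=trace.mean,
        pp=trace.sbp - trace.dbp,
        hr=hr,
        co=sv * hr / 1000.0,
        sv=sv,
        ef=supplements["ef"],
        sw=supplements["sw"],
    )
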