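"""Single-segment Windkessel vessel model: inflow waveform and pressure ODE.

The vessel segment is a lumped RCI (resistance-compliance-inertance) element
driven by a half-sinusoid ejection waveform against a constant downstream
pressure ``P_next``.  Eliminating flow and volume from the bond-graph state
equations

    dV/dt = Q_in - Q,    d(lambda)/dt = P - P_next - R*Q,
    Q = lambda / I,      P = V / C,

gives the second-order pressure equation

    I*C * P'' + R*C * P' + P = I * Q_in' + R * Q_in + P_next.

This module provides the closed-form solution of that equation on each
branch of the piecewise-sinusoidal inflow (systole) and for zero inflow
(diastole), three conventions for assembling the branches into a full-cycle
trace, a fixed-step RK4 integrator of the first-order system as an
independent numeric oracle, and ``forward_bp`` mapping (R, C) to the
(SBP, DBP) summary pair used by the inverse estimator.

Units: seconds, mmHg, mmHg*s/mL (R), mL/mmHg (C), mmHg*s^2/mL (I).  The
inflow amplitude is carried in model flow units (its time integral is not
calibrated to a physiological stroke volume; see the methods note).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConvergenceError,
    DegenerateRootError,
    ModelInconsistencyError,
    TimeDomainError,
)

__all__ = [
    "CardiacTiming",
    "VesselParams",
    "FlowWaveform",
    "SolutionCoefficients",
    "StateVector",
    "PressureTrace",
    "ClosedFormCycle",
    "input_flow",
    "characteristic_roots",
    "systolic_pressure",
    "diastolic_pressure",
    "assemble_cycle",
    "solve_ode_numeric",
    "forward_bp",
    "ADMISSIBLE_R",
    "ADMISSIBLE_C",
    "DEFAULT_INERTANCE",
    "DEFAULT_P_NEXT",
    "SBP_SAMPLE_TIME",
]

#: Admissible (R, C) box for which the model conventions are validated.
ADMISSIBLE_R = (1.55, 3.60)
ADMISSIBLE_C = (0.30, 0.60)

DEFAULT_INERTANCE = 0.23
DEFAULT_P_NEXT = 30.0

#: Fixed systolic sampling time (s) defining SBP for a 0.3 s systole;
#: scaled proportionally for other systole durations.
SBP_SAMPLE_TIME = 0.14

#: Coefficient policies understood by :func:`assemble_cycle` / :func:`forward_bp`.
POLICIES = ("matched", "continuity", "literal")
BP_MODES = ("fixed_time", "extremum")


@dataclass(frozen=True)
class CardiacTiming:
    """One cardiac cycle: total length and ejection (systole) duration, s."""

    cycle_length: float = 0.8
    systole_duration: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.systole_duration < self.cycle_length:
            raise ValueError(
                "require 0 < systole_duration < cycle_length, got "
                f"systole={self.systole_duration}, cycle={self.cycle_length}"
            )


@dataclass(frozen=True)
class VesselParams:
    """Lumped vessel parameters: the unknowns of the inverse problem.

    ``R`` is vascular resistance (mmHg*s/mL), ``C`` vascular compliance
    (mL/mmHg), ``I`` blood inertance (mmHg*s^2/mL) and ``p_next`` the
    constant downstream boundary pressure (mmHg).
    """

    R: float
    C: float
    I: float = DEFAULT_INERTANCE
    p_next: float = DEFAULT_P_NEXT

    def __post_init__(self) -> None:
        for name in ("R", "C", "I"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def discriminant(self) -> float:
        """R^2 C^2 - 4 C I: sign classifies the characteristic roots."""
        return self.R**2 * self.C**2 - 4.0 * self.C * self.I


@dataclass(frozen=True)
class FlowWaveform:
    """Piecewise-sinusoidal ejection waveform (model flow units).

    Zero at t = 0 and throughout diastole; a half-sinusoid shoulder with a
    double-frequency mid-systolic bump.  Continuous at all three interior
    breakpoints (Ts/4, 3Ts/4, Ts).
    """

    amplitude: float = 70.0
    timing: CardiacTiming = field(default_factory=CardiacTiming)


@dataclass(frozen=True)
class SolutionCoefficients:
    """Homogeneous-solution coefficients for the closed-form branches.

    ``k1``/``k2`` multiply the slow/fast root exponentials in systole,
    ``k3``/``k4`` in diastole.  The defaults are the literal constants of
    the source convention (used by the ``literal`` policy only; the other
    policies solve for coefficients and ignore this object).
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = -200.0
    k4: float = -400.0


@dataclass(frozen=True)
class StateVector:
    """First-order state (volume V, pressure momentum lambda).

    Pressure and flow are derived exactly: P = V/C, Q = lambda/I.
    """

    V: float
    lam: float

    def pressure(self, p: VesselParams) -> float:
        return self.V / p.C

    def flow(self, p: VesselParams) -> float:
        return self.lam / p.I


@dataclass
class PressureTrace:
    """Sampled pressure over one cycle: strictly increasing times, mmHg."""

    times: np.ndarray
    pressures: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.times.shape != self.pressures.shape or self.times.ndim != 1:
            raise ValueError("times and pressures must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def sbp(self) -> float:
        return float(self.pressures.max())

    @property
    def dbp(self) -> float:
        return float(self.pressures.min())

    @property
    def mean(self) -> float:
        """Time-averaged pressure (trapezoidal)."""
        span = self.times[-1] - self.times[0]
        return float(np.trapezoid(self.pressures, self.times) / span)

    def to_text(self, path) -> None:
        """Write a 2-column delimited trace (time_s, pressure_mmHg)."""
        np.savetxt(
            path,
            np.column_stack([self.times, self.pressures]),
            header="time_s\tpressure_mmHg",
            delimiter="\t",
            comments="",
        )

    @classmethod
    def from_text(cls, path) -> "PressureTrace":
        arr = np.loadtxt(path, skiprows=1)
        return cls(times=arr[:, 0], pressures=arr[:, 1])


# ---------------------------------------------------------------------------
# Inflow waveform
# ---------------------------------------------------------------------------

def input_flow(t, wf: FlowWaveform | None = None):
    """Evaluate the ejection waveform at time ``t`` (scalar or array).

    Branches (Ts = systole duration, A = amplitude):

    * ``[0, Ts/4)``      A sin(pi t / Ts)
    * ``[Ts/4, 3Ts/4)``  A sin(pi/4) + (A/2) sin(2 pi (t - Ts/4) / Ts)
    * ``[3Ts/4, Ts)``    A sin(pi t / Ts)
    * ``[Ts, Tc]``       0

    Raises :class:`TimeDomainError` for t outside [0, cycle_length].
    """
    wf = wf or FlowWaveform()
    ts, tc = wf.timing.systole_duration, wf.timing.cycle_length
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > tc):
        raise TimeDomainError(f"t must lie in [0, {tc}]")
    a = wf.amplitude
    out = np.zeros_like(t_arr)
    shoulder = (t_arr < ts / 4) | ((t_arr >= 3 * ts / 4) & (t_arr < ts))
    out[shoulder] = a * np.sin(np.pi * t_arr[shoulder] / ts)
    mid = (t_arr >= ts / 4) & (t_arr < 3 * ts / 4)
    out[mid] = a * np.sin(np.pi / 4) + (a / 2.0) * np.sin(
        2.0 * np.pi * (t_arr[mid] - ts / 4) / ts
    )
    return out if np.ndim(t) else float(out)


def _flow_scalar(t: float, amp: float, ts: float, tc: float) -> float:
    """Scalar inflow for the RK4 oracle (pure-python hot path).

    Kept consistent with :func:`input_flow`; a test asserts agreement.
    """
    t = t % tc
    if t >= ts:
        return 0.0
    if t < ts / 4 or t >= 3 * ts / 4:
        return amp * math.sin(math.pi * t / ts)
    return amp * math.sin(math.pi / 4) + (amp / 2.0) * math.sin(
        2.0 * math.pi * (t - ts / 4) / ts
    )


# ---------------------------------------------------------------------------
# Characteristic roots and homogeneous basis
# ---------------------------------------------------------------------------

def characteristic_roots(p: VesselParams):
    """Roots of I C s^2 + R C s + 1 = 0, slow root first.

    Returns a pair of floats for a positive discriminant, or a conjugate
    pair of complex numbers (positive-imaginary first) for a negative one.
    Both roots always have negative real part (the element is passive).
    Raises :class:`DegenerateRootError` on a repeated root.
    """
    disc = p.discriminant
    two_ci = 2.0 * p.C * p.I
    if disc == 0.0:
        raise DegenerateRootError(
            f"repeated characteristic root at R={p.R}, C={p.C}, I={p.I}"
        )
    if disc > 0:
        sq = math.sqrt(disc)
        return (-p.R * p.C + sq) / two_ci, (-p.R * p.C - sq) / two_ci
    sq = math.sqrt(-disc)
    s = complex(-p.R * p.C / two_ci, sq / two_ci)
    return s, s.conjugate()


class _HomogeneousBasis:
    """Real-valued homogeneous solution basis, evaluated at a time offset.

    For real distinct roots the basis is (e^{s1 dt}, e^{s2 dt}); for a
    complex pair -alpha +/- i beta it is
    (e^{-alpha dt} cos(beta dt), e^{-alpha dt} sin(beta dt)).
    """

    def __init__(self, p: VesselParams):
        s1, s2 = characteristic_roots(p)
        self.complex_pair = isinstance(s1, complex)
        if self.complex_pair:
            self.alpha, self.beta = -s1.real, s1.imag
        else:
            self.s1, self.s2 = s1, s2

    def value(self, dt):
        dt = np.asarray(dt, dtype=float)
        if self.complex_pair:
            env = np.exp(-self.alpha * dt)
            return env * np.cos(self.beta * dt), env * np.sin(self.beta * dt)
        return np.exp(self.s1 * dt), np.exp(self.s2 * dt)

    def deriv(self, dt):
        dt = np.asarray(dt, dtype=float)
        if self.complex_pair:
            env = np.exp(-self.alpha * dt)
            c, s = np.cos(self.beta * dt), np.sin(self.beta * dt)
            return (
                env * (-self.alpha * c - self.beta * s),
                env * (-self.alpha * s + self.beta * c),
            )
        return self.s1 * np.exp(self.s1 * dt), self.s2 * np.exp(self.s2 * dt)

    def literal_coeffs(self, k_slow: float, k_fast: float, t0: float):
        """Shifted-basis coefficients representing Re(k_slow e^{s1 t} + k_fast e^{s2 t}).

        For a complex pair with real k's the real part collapses to
        (k_slow + k_fast) e^{-alpha t} cos(beta t).
        """
        if self.complex_pair:
            k = k_slow + k_fast
            env = math.exp(-self.alpha * t0)
            return k * env * math.cos(self.beta * t0), -k * env * math.sin(self.beta * t0)
        return k_slow * math.exp(self.s1 * t0), k_fast * math.exp(self.s2 * t0)


# ---------------------------------------------------------------------------
# Branch particular solutions
# ---------------------------------------------------------------------------

class _Branch:
    """One inflow branch: Q(t) = a + b sin(w t) + c cos(w t) on [t0, t1).

    The steady particular response of the pressure ODE to the corresponding
    forcing F = I Q' + R Q + p_next is  g0 + Re(gc e^{i w t})  with
    g0 = R a + p_next and gc = H(iw) (A_cos - i A_sin), where A_cos/A_sin
    are the cosine/sine components of F and H(iw) = 1/(1 - I C w^2 + i R C w).
    """

    __slots__ = ("t0", "t1", "omega", "g0", "gc")

    def __init__(self, p: VesselParams, t0, t1, a, b, c, omega):
        self.t0, self.t1, self.omega = t0, t1, omega
        self.g0 = p.R * a + p.p_next
        a_cos = p.R * c + p.I * b * omega
        a_sin = p.R * b - p.I * c * omega
        h = 1.0 / (1.0 - p.I * p.C * omega**2 + 1j * p.R * p.C * omega)
        self.gc = h * (a_cos - 1j * a_sin)

    def particular(self, t):
        return self.g0 + np.real(self.gc * np.exp(1j * self.omega * np.asarray(t, float)))

    def particular_deriv(self, t):
        return np.real(
            1j * self.omega * self.gc * np.exp(1j * self.omega * np.asarray(t, float))
        )


def _branches(p: VesselParams, timing: CardiacTiming, wf: FlowWaveform):
    ts, tc, a = timing.systole_duration, timing.cycle_length, wf.amplitude
    w1, w2 = np.pi / ts, 2.0 * np.pi / ts
    # mid branch: A sin(pi/4) + (A/2) sin(w2 (t - ts/4)) == A sin(pi/4) - (A/2) cos(w2 t)
    return [
        _Branch(p, 0.0, ts / 4, 0.0, a, 0.0, w1),
        _Branch(p, ts / 4, 3 * ts / 4, a * math.sin(math.pi / 4), 0.0, -a / 2.0, w2),
        _Branch(p, 3 * ts / 4, ts, 0.0, a, 0.0, w1),
        _Branch(p, ts, tc, 0.0, 0.0, 0.0, 1.0),
    ]


# ---------------------------------------------------------------------------
# Literal closed-form branch solutions
# ---------------------------------------------------------------------------

def _literal_homogeneous(t, p: VesselParams, k_slow: float, k_fast: float):
    s1, s2 = characteristic_roots(p)
    t = np.asarray(t, dtype=float)
    return np.real(k_slow * np.exp(s1 * t) + k_fast * np.exp(s2 * t))


def systolic_pressure(
    t,
    p: VesselParams,
    coeffs: SolutionCoefficients | None = None,
    timing: CardiacTiming | None = None,
    wf: FlowWaveform | None = None,
):
    """Closed-form mid-systolic pressure (mmHg) at time ``t``.

    Valid on the mid-systole forcing branch t in [Ts/4, 3Ts/4] only; the
    homogeneous part uses the two characteristic roots (real part taken for
    a complex pair with real coefficients), the particular part is the
    steady sinusoidal response plus constant offset.
    """
    coeffs = coeffs or SolutionCoefficients()
    timing = timing or CardiacTiming()
    wf = wf or FlowWaveform(timing=timing)
    ts = timing.systole_duration
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < ts / 4 - 1e-12) or np.any(t_arr > 3 * ts / 4 + 1e-12):
        raise TimeDomainError(f"t must lie in mid-systole [{ts / 4}, {3 * ts / 4}]")
    branch = _branches(p, timing, wf)[1]
    out = _literal_homogeneous(t_arr, p, coeffs.k1, coeffs.k2) + branch.particular(t_arr)
    return out if np.ndim(t) else float(out)


def diastolic_pressure(
    t,
    p: VesselParams,
    coeffs: SolutionCoefficients | None = None,
    timing: CardiacTiming | None = None,
):
    """Closed-form diastolic pressure (mmHg): free decay toward ``p_next``.

    Valid on t in [systole_duration, cycle_length] (zero inflow).
    """
    coeffs = coeffs or SolutionCoefficients()
    timing = timing or CardiacTiming()
    ts, tc = timing.systole_duration, timing.cycle_length
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < ts - 1e-12) or np.any(t_arr > tc + 1e-12):
        raise TimeDomainError(f"t must lie in diastole [{ts}, {tc}]")
    out = _literal_homogeneous(t_arr, p, coeffs.k3, coeffs.k4) + p.p_next
    return out if np.ndim(t) else float(out)


# ---------------------------------------------------------------------------
# Assembled full-cycle closed form
# ---------------------------------------------------------------------------

class ClosedFormCycle:
    """Piecewise closed-form pressure over one cycle.

    Built by :func:`assemble_cycle`; callable on scalar or array times in
    [0, cycle_length].  Each branch k carries homogeneous coefficients
    (A_k, B_k) in a basis shifted to the branch start (for conditioning).
    """

    def __init__(self, p, timing, wf, policy, branches, basis, coefs):
        self.params = p
        self.timing = timing
        self.waveform = wf
        self.policy = policy
        self._branches = branches
        self._basis = basis
        self._coefs = coefs  # shape (4, 2)

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        tc = self.timing.cycle_length
        if np.any(t_arr < -1e-12) or np.any(t_arr > tc + 1e-12):
            raise TimeDomainError(f"t must lie in [0, {tc}]")
        out = np.empty_like(t_arr)
        for k, br in enumerate(self._branches):
            hi = (t_arr <= br.t1) if k == 3 else (t_arr < br.t1)
            m = (t_arr >= br.t0) & hi
            if not m.any():
                continue
            h1, h2 = self._basis.value(t_arr[m] - br.t0)
            a, b = self._coefs[k]
            out[m] = a * h1 + b * h2 + br.particular(t_arr[m])
        return out if np.ndim(t) else float(out[0])

    def derivative(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t_arr)
        for k, br in enumerate(self._branches):
            hi = (t_arr <= br.t1) if k == 3 else (t_arr < br.t1)
            m = (t_arr >= br.t0) & hi
            if not m.any():
                continue
            d1, d2 = self._basis.deriv(t_arr[m] - br.t0)
            a, b = self._coefs[k]
            out[m] = a * d1 + b * d2 + br.particular_deriv(t_arr[m])
        return out if np.ndim(t) else float(out[0])

    def sample(self, n: int = 2001) -> PressureTrace:
        t = np.linspace(0.0, self.timing.cycle_length, n)
        return PressureTrace(times=t, pressures=self(t))


def _solve_2x2(basis, dt, rhs_val, rhs_der):
    h1, h2 = basis.value(dt)
    d1, d2 = basis.deriv(dt)
    mat = np.array([[h1, h2], [d1, d2]], dtype=float)
    return np.linalg.solve(mat, np.array([rhs_val, rhs_der], dtype=float))


def assemble_cycle(
    p: VesselParams,
    timing: CardiacTiming | None = None,
    wf: FlowWaveform | None = None,
    policy: str = "matched",
    coeffs: SolutionCoefficients | None = None,
) -> ClosedFormCycle:
    """Assemble the piecewise closed-form pressure over one full cycle.

    Policies:

    * ``"matched"`` (default) — the literal mid-systole solution with
      k1 = k2 = 1 (or ``coeffs``), continued C1-continuously through the
      remaining branches.  Non-periodic single-beat trace; this convention
      defines the mapping surfaces used by the inverse estimator.
    * ``"continuity"`` — homogeneous coefficients of all four branches
      solved jointly so the trace is C1 at every breakpoint *and*
      cycle-periodic: the exact steady state of the driven ODE, matching
      the numeric oracle.
    """
    timing = timing or CardiacTiming()
    wf = wf or FlowWaveform(timing=timing)
    if policy not in ("matched", "continuity"):
        raise ValueError(f"unknown assembly policy {policy!r}")
    branches = _branches(p, timing, wf)
    basis = _HomogeneousBasis(p)
    coefs = np.zeros((4, 2))

    if policy == "matched":
        coeffs = coeffs or SolutionCoefficients()
        coefs[1] = basis.literal_coeffs(coeffs.k1, coeffs.k2, branches[1].t0)

        def branch_state(k, tau):
            h1, h2 = basis.value(tau - branches[k].t0)
            d1, d2 = basis.deriv(tau - branches[k].t0)
            a, b = coefs[k]
            return (
                a * h1 + b * h2 + branches[k].particular(tau),
                a * d1 + b * d2 + branches[k].particular_deriv(tau),
            )

        # forward continuation: branch 2 at 3Ts/4, branch 3 at Ts
        for k in (2, 3):
            tau = branches[k].t0
            val, der = branch_state(k - 1, tau)
            coefs[k] = _solve_2x2(
                basis,
                0.0,
                val - branches[k].particular(tau),
                der - branches[k].particular_deriv(tau),
            )
        # backward continuation: branch 0 matched to branch 1 at Ts/4
        tau = branches[1].t0
        val, der = branch_state(1, tau)
        coefs[0] = _solve_2x2(
            basis,
            tau,
            val - branches[0].particular(tau),
            der - branches[0].particular_deriv(tau),
        )
    else:  # continuity: global 8x8 with periodicity closure
        mat = np.zeros((8, 8))
        rhs = np.zeros(8)
        row = 0
        h0 = basis.value(0.0)
        d0 = basis.deriv(0.0)
        for k in range(3):
            tau = branches[k].t1
            hl, dl = basis.value(tau - branches[k].t0), basis.deriv(tau - branches[k].t0)
            mat[row, 2 * k : 2 * k + 2] = hl
            mat[row, 2 * k + 2 : 2 * k + 4] = (-h0[0], -h0[1])
            rhs[row] = branches[k + 1].particular(tau) - branches[k].particular(tau)
            row += 1
            mat[row, 2 * k : 2 * k + 2] = dl
            mat[row, 2 * k + 2 : 2 * k + 4] = (-d0[0], -d0[1])
            rhs[row] = branches[k + 1].particular_deriv(tau) - branches[k].particular_deriv(tau)
            row += 1
        tc = timing.cycle_length
        dt4 = tc - branches[3].t0
        h4, d4 = basis.value(dt4), basis.deriv(dt4)
        mat[row, 0:2] = h0
        mat[row, 6:8] = (-h4[0], -h4[1])
        rhs[row] = branches[3].particular(tc) - branches[0].particular(0.0)
        row += 1
        mat[row, 0:2] = d0
        mat[row, 6:8] = (-d4[0], -d4[1])
        rhs[row] = branches[3].particular_deriv(tc) - branches[0].particular_deriv(0.0)
        coefs[:] = np.linalg.solve(mat, rhs).reshape(4, 2)

    return ClosedFormCycle(p, timing, wf, policy, branches, basis, coefs)


# ---------------------------------------------------------------------------
# Numeric oracle
# ---------------------------------------------------------------------------

def solve_ode_numeric(
    p: VesselParams,
    timing: CardiacTiming | None = None,
    wf: FlowWaveform | None = None,
    init: StateVector | None = None,
    n_cycles: int = 1,
    max_cycles: int = 200,
    steps_per_cycle: int = 2000,
    tol: float = 1e-4,
) -> PressureTrace:
    """Integrate the first-order system to periodic steady state (RK4).

    Fixed-step classical 4th-order integration with ``steps_per_cycle``
    steps per cycle, run cycle by cycle for at least ``n_cycles`` and until
    the maximum absolute pressure difference between successive cycles drops
    below ``tol`` (mmHg).  Returns the last cycle's trace (samples at the
    step times, endpoints inclusive).

    Raises :class:`ConvergenceError` if the transient has not decayed after
    ``max_cycles`` cycles.
    """
    timing = timing or CardiacTiming()
    wf = wf or FlowWaveform(timing=timing)
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if steps_per_cycle < 1000:
        raise ValueError("steps_per_cycle must be >= 1000")
    ts, tc, amp = timing.systole_duration, timing.cycle_length, wf.amplitude
    r_val, c_val, i_val, p_next = p.R, p.C, p.I, p.p_next
    if init is None:
        # warm start at the analytic mean pressure to shorten the transient
        mean_q = amp * ts * (1.0 / math.pi + math.sqrt(2) / 4.0 + 3.0 / (4.0 * math.pi)) / tc
        init = StateVector(V=c_val * (p_next + r_val * mean_q), lam=0.0)
    v, lam = init.V, init.lam
    h = tc / steps_per_cycle

    def deriv(t, v, lam):
        q_out = lam / i_val
        return _flow_scalar(t, amp, ts, tc) - q_out, v / c_val - p_next - r_val * q_out

    prev = None
    trace = None
    for cycle in range(max_cycles):
        tr = [0.0] * (steps_per_cycle + 1)
        for i in range(steps_per_cycle):
            t = i * h
            tr[i] = v / c_val
            k1v, k1l = deriv(t, v, lam)
            k2v, k2l = deriv(t + h / 2, v + h / 2 * k1v, lam + h / 2 * k1l)
            k3v, k3l = deriv(t + h / 2, v + h / 2 * k2v, lam + h / 2 * k2l)
            k4v, k4l = deriv(t + h, v + h * k3v, lam + h * k3l)
            v += h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
            lam += h / 6 * (k1l + 2 * k2l + 2 * k3l + k4l)
        tr[steps_per_cycle] = v / c_val
        trace = np.array(tr)
        if cycle + 1 >= n_cycles and prev is not None:
            if float(np.max(np.abs(trace - prev))) < tol:
                times = np.arange(steps_per_cycle + 1) * h
                return PressureTrace(times=times, pressures=trace)
        prev = trace
    raise ConvergenceError(
        f"no periodic steady state within {max_cycles} cycles (tol={tol} mmHg)"
    )


# ---------------------------------------------------------------------------
# Forward BP summary
# ---------------------------------------------------------------------------

def forward_bp(
    p: VesselParams,
    mode: str = "fixed_time",
    policy: str = "matched",
    timing: CardiacTiming | None = None,
    wf: FlowWaveform | None = None,
    coeffs: SolutionCoefficients | None = None,
    n_samples: int = 2001,
) -> tuple[float, float]:
    """Map (R, C) to the (SBP, DBP) pair, mmHg.

    ``mode="fixed_time"`` evaluates the assembled cycle at the fixed
    sampling times (t = 0.14 s for SBP, scaled with systole duration, and
    t = cycle_length for DBP); ``mode="extremum"`` takes the max/min of a
    densely sampled trace.  ``policy`` selects the coefficient convention
    (see :func:`assemble_cycle`); ``policy="literal"`` uses the literal branch
    solutions with the printed constants and supports sampling on the
    covered branches only.

    Warns (does not fail) if (R, C) lies outside the admissible box.
    Raises :class:`ModelInconsistencyError` if SBP <= DBP.
    """
    timing = timing or CardiacTiming()
    wf = wf or FlowWaveform(timing=timing)
    if mode not in BP_MODES:
        raise ValueError(f"unknown bp mode {mode!r}")
    if policy not in POLICIES:
        raise ValueError(f"unknown coefficient policy {policy!r}")
    if not (ADMISSIBLE_R[0] <= p.R <= ADMISSIBLE_R[1]) or not (
        ADMISSIBLE_C[0] <= p.C <= ADMISSIBLE_C[1]
    ):
        warnings.warn(
            f"(R={p.R}, C={p.C}) outside the admissible box "
            f"{ADMISSIBLE_R} x {ADMISSIBLE_C}; model conventions unvalidated there",
            stacklevel=2,
        )
    ts, tc = timing.systole_duration, timing.cycle_length
    t_sbp = SBP_SAMPLE_TIME * (ts / 0.3)

    if policy == "literal":
        cs = coeffs or SolutionCoefficients()
        if mode == "fixed_time":
            sbp = float(systolic_pressure(t_sbp, p, cs, timing, wf))
            dbp = float(diastolic_pressure(tc, p, cs, timing))
        else:
            t_sys = np.linspace(ts / 4, 3 * ts / 4, n_samples)
            t_dia = np.linspace(ts, tc, n_samples)
            sbp = float(np.max(systolic_pressure(t_sys, p, cs, timing, wf)))
            dbp = float(np.min(diastolic_pressure(t_dia, p, cs, timing)))
    else:
        cycle = assemble_cycle(p, timing, wf, policy=policy, coeffs=coeffs)
        if mode == "fixed_time":
            sbp = cycle(t_sbp)
            dbp = cycle(tc)
        else:
            trace = cycle.sample(n_samples)
            sbp, dbp = trace.sbp, trace.dbp

    if sbp <= dbp:
        raise ModelInconsistencyError(
            f"SBP ({sbp:.2f}) <= DBP ({dbp:.2f}) at R={p.R}, C={p.C}; "
            "coefficient convention failure"
        )
    return sbp, dbp
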