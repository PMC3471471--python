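"""Unit and property tests for the vessel pressure model.

The closed-form branches are checked against two independent oracles: a
finite-difference residual of the governing second-order ODE, and a
fixed-step RK4 integration of the first-order system.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import windkessel_hf as wk
from windkessel_hf.exceptions import (
    DegenerateRootError,
    TimeDomainError,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fd_ode_residual(pressure_fn, t, p, forcing_fn, h=5e-4):
    """|I C P'' + R C P' + P - F| via 4th-order central differences."""
    t = np.asarray(t, dtype=float)
    stencil = np.array([-2, -1, 0, 1, 2])
    vals = np.stack([pressure_fn(t + k * h) for k in stencil])
    p0 = vals[2]
    p1 = (vals[0] - 8 * vals[1] + 8 * vals[3] - vals[4]) / (12 * h)
    p2 = (-vals[0] + 16 * vals[1] - 30 * vals[2] + 16 * vals[3] - vals[4]) / (12 * h**2)
    lhs = p.I * p.C * p2 + p.R * p.C * p1 + p0
    rhs = forcing_fn(t)
    terms = np.max(
        np.abs(np.stack([p.I * p.C * p2, p.R * p.C * p1, p0, rhs])), axis=0
    )
    return np.abs(lhs - rhs), terms


def midsystole_forcing(p, wf, h=5e-4):
    """F = I Q' + R Q + p_next on the mid-systole branch (FD for Q')."""

    def forcing(t):
        q = wk.input_flow(t, wf)
        qp = (
            wk.input_flow(t - 2 * h, wf)
            - 8 * wk.input_flow(t - h, wf)
            + 8 * wk.input_flow(t + h, wf)
            - wk.input_flow(t + 2 * h, wf)
        ) / (12 * h)
        return p.I * qp + p.R * q + p.p_next

    return forcing


GRID_SAMPLES = [
    (1.55, 0.30),  # complex characteristic roots
    (1.55, 0.60),
    (2.00, 0.45),
    (2.50, 0.45),
    (3.60, 0.30),
    (3.60, 0.60),
]


# ---------------------------------------------------------------------------
# inflow waveform
# ---------------------------------------------------------------------------

class TestInputFlow:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.0, 0.0),
            (0.5, 0.0),   # diastole
            (0.3, 0.0),
            (0.15, 70 * math.sin(math.pi / 4) + 35 * math.sin(math.pi / 2)),
        ],
    )
    def test_values(self, t, expected):
        assert wk.input_flow(t) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bp", [0.075, 0.225])
    def test_continuity_at_breakpoints(self, bp):
        eps = 1e-9
        left = wk.input_flow(bp - eps)
        right = wk.input_flow(bp + eps)
        # one-sided limits agree with the shared breakpoint value to within
        # slope * eps (the waveform is continuous, not differentiable, there)
        assert left == pytest.approx(70 * math.sin(math.pi / 4), abs=1e-5)
        assert right == pytest.approx(left, abs=1e-5)

    def test_continuity_at_end_systole(self):
        assert wk.input_flow(0.3 - 1e-9) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("t", [-0.1, 0.81])
    def test_domain_error(self, t):
        with pytest.raises(TimeDomainError):
            wk.input_flow(t)

    def test_scalar_matches_array(self):
        t = np.linspace(0, 0.8, 257)
        arr = wk.input_flow(t)
        assert arr == pytest.approx([wk.input_flow(ti) for ti in t])


# ---------------------------------------------------------------------------
# characteristic roots
# ---------------------------------------------------------------------------

class TestCharacteristicRoots:
    def test_hand_computed_example(self):
        s1, s2 = wk.characteristic_roots(wk.VesselParams(R=2.0, C=0.45))
        assert s1 == pytest.approx(-1.3077, abs=5e-4)
        assert s2 == pytest.approx(-7.388, abs=5e-3)

    def test_complex_case(self):
        s1, s2 = wk.characteristic_roots(wk.VesselParams(R=1.55, C=0.30))
        assert isinstance(s1, complex)
        assert s2 == s1.conjugate()
        assert s1.real < 0

    def test_degenerate_root_error(self):
        # R^2 C^2 == 4 C I exactly when C == 4 I / R^2
        with pytest.raises(DegenerateRootError):
            wk.characteristic_roots(wk.VesselParams(R=2.0, C=0.23, I=0.23))

    @given(
        r=st.floats(1.0, 5.0),
        c=st.floats(0.2, 0.8),
        inertance=st.floats(0.1, 0.5),
    )
    def test_vieta_and_stability(self, r, c, inertance):
        p = wk.VesselParams(R=r, C=c, I=inertance)
        try:
            s1, s2 = wk.characteristic_roots(p)
        except DegenerateRootError:
            return
        assert complex(s1 * s2).real == pytest.approx(1 / (inertance * c), rel=1e-9)
        assert complex(s1 + s2).real == pytest.approx(-r / inertance, rel=1e-9)
        assert complex(s1).real < 0 and complex(s2).real < 0


# ---------------------------------------------------------------------------
# closed-form branches satisfy the ODE
# ---------------------------------------------------------------------------

class TestClosedFormBranches:
    @pytest.mark.parametrize("r,c", GRID_SAMPLES)
    def test_systolic_ode_residual(self, r, c):
        p = wk.VesselParams(R=r, C=c)
        wf = wk.FlowWaveform()
        t = np.linspace(0.075 + 2e-3, 0.225 - 2e-3, 50)
        resid, terms = fd_ode_residual(
            lambda tt: wk.systolic_pressure(tt, p), t, p, midsystole_forcing(p, wf)
        )
        assert np.max(resid / np.max(terms)) < 1e-6

    @pytest.mark.parametrize("r,c", GRID_SAMPLES)
    def test_diastolic_ode_residual(self, r, c):
        p = wk.VesselParams(R=r, C=c)
        t = np.linspace(0.31, 0.79, 50)
        resid, terms = fd_ode_residual(
            lambda tt: wk.diastolic_pressure(tt, p), t, p, lambda tt: np.full_like(tt, p.p_next)
        )
        assert np.max(resid / np.max(terms)) < 1e-6

    def test_zero_homogeneous_systolic_is_particular(self):
        """With K1 = K2 = 0 only the particular solution remains; it still
        satisfies the forced ODE."""
        p = wk.VesselParams(R=2.0, C=0.45)
        wf = wk.FlowWaveform()
        coeffs = wk.SolutionCoefficients(k1=0.0, k2=0.0)
        t = np.linspace(0.08, 0.22, 25)
        resid, terms = fd_ode_residual(
            lambda tt: wk.systolic_pressure(tt, p, coeffs), t, p, midsystole_forcing(p, wf)
        )
        assert np.max(resid / np.max(terms)) < 1e-6

    def test_zero_coefficients_diastole_is_equilibrium(self):
        p = wk.VesselParams(R=2.0, C=0.45)
        coeffs = wk.SolutionCoefficients(k3=0.0, k4=0.0)
        t = np.linspace(0.3, 0.8, 20)
        assert wk.diastolic_pressure(t, p, coeffs) == pytest.approx([30.0] * 20)

    @pytest.mark.parametrize("fn,t_bad", [("sys", 0.05), ("sys", 0.24), ("dia", 0.2)])
    def test_branch_domain_errors(self, fn, t_bad):
        p = wk.VesselParams(R=2.0, C=0.45)
        with pytest.raises(TimeDomainError):
            if fn == "sys":
                wk.systolic_pressure(t_bad, p)
            else:
                wk.diastolic_pressure(t_bad, p)

    @pytest.mark.parametrize("r,c", [(2.0, 0.45), (3.0, 0.35), (1.8, 0.55)])
    def test_systolic_argmax_interior(self, r, c):
        """The mid-systolic pressure peak lies strictly inside the branch."""
        p = wk.VesselParams(R=r, C=c)
        t = np.linspace(0.075, 0.225, 3001)
        vals = wk.systolic_pressure(t, p)
        k = int(np.argmax(vals))
        assert 0 < k < len(t) - 1

    @pytest.mark.parametrize("r,c", [(2.0, 0.45), (2.8, 0.35)])
    def test_matched_diastole_monotone_non_increasing(self, r, c):
        p = wk.VesselParams(R=r, C=c)
        cycle = wk.assemble_cycle(p, policy="matched")
        t = np.linspace(0.4, 0.8, 400)
        vals = cycle(t)
        assert np.all(np.diff(vals) <= 1e-12)


# ---------------------------------------------------------------------------
# assembled cycles
# ---------------------------------------------------------------------------

class TestAssembledCycle:
    @pytest.mark.parametrize("policy", ["matched", "continuity"])
    @pytest.mark.parametrize("r,c", [(2.0, 0.45), (1.55, 0.30), (3.6, 0.6)])
    def test_c1_continuity_at_breakpoints(self, policy, r, c):
        cycle = wk.assemble_cycle(wk.VesselParams(R=r, C=c), policy=policy)
        eps = 1e-9
        for bp in (0.075, 0.225, 0.3):
            assert cycle(bp + eps) == pytest.approx(cycle(bp - eps), abs=1e-5)
            assert cycle.derivative(bp + eps) == pytest.approx(
                cycle.derivative(bp - eps), abs=1e-3
            )

    @pytest.mark.parametrize("r,c", [(2.0, 0.45), (1.55, 0.30), (3.6, 0.6)])
    def test_continuity_cycle_is_periodic(self, r, c):
        cycle = wk.assemble_cycle(wk.VesselParams(R=r, C=c), policy="continuity")
        assert cycle(0.0) == pytest.approx(cycle(0.8), abs=1e-8)
        assert cycle.derivative(0.0) == pytest.approx(cycle.derivative(0.8), abs=1e-6)

    @pytest.mark.parametrize("r,c", GRID_SAMPLES)
    def test_continuity_cycle_matches_numeric_oracle(self, r, c):
        p = wk.VesselParams(R=r, C=c)
        cycle = wk.assemble_cycle(p, policy="continuity")
        trace = wk.solve_ode_numeric(p)
        assert np.max(np.abs(cycle(trace.times) - trace.pressures)) < 0.5

    def test_matched_midsystole_equals_literal_solution(self):
        """The matched assembly reproduces the literal k1 = k2 = 1 branch."""
        p = wk.VesselParams(R=2.5, C=0.5)
        cycle = wk.assemble_cycle(p, policy="matched")
        t = np.linspace(0.08, 0.22, 30)
        assert cycle(t) == pytest.approx(wk.systolic_pressure(t, p), abs=1e-9)


# ---------------------------------------------------------------------------
# numeric oracle
# ---------------------------------------------------------------------------

class TestNumericOracle:
    def test_equilibrium_fixed_point(self):
        p = wk.VesselParams(R=2.0, C=0.45)
        wf = wk.FlowWaveform(amplitude=0.0)
        init = wk.StateVector(V=p.p_next * p.C, lam=0.0)
        trace = wk.solve_ode_numeric(p, wf=wf, init=init)
        assert trace.pressures == pytest.approx(np.full_like(trace.pressures, 30.0), abs=1e-9)

    def test_steady_state_is_cycle_periodic(self):
        trace = wk.solve_ode_numeric(wk.VesselParams(R=2.0, C=0.45))
        assert abs(trace.pressures[0] - trace.pressures[-1]) < 1e-3

    @pytest.mark.parametrize("r,c", [(2.0, 0.45), (3.0, 0.55)])
    def test_mean_pressure_above_boundary(self, r, c):
        trace = wk.solve_ode_numeric(wk.VesselParams(R=r, C=c))
        assert trace.mean >= 30.0

    def test_oracle_flow_matches_public_waveform(self):
        from windkessel_hf.waveform import _flow_scalar

        wf = wk.FlowWaveform()
        t = np.linspace(0, 0.8, 641)
        got = [_flow_scalar(ti, 70.0, 0.3, 0.8) for ti in t]
        assert got == pytest.approx(list(wk.input_flow(t)), abs=1e-12)

    def test_invalid_arguments(self):
        p = wk.VesselParams(R=2.0, C=0.45)
        with pytest.raises(ValueError):
            wk.solve_ode_numeric(p, n_cycles=0)
        with pytest.raises(ValueError):
            wk.solve_ode_numeric(p, steps_per_cycle=100)


# ---------------------------------------------------------------------------
# forward BP summary
# ---------------------------------------------------------------------------

class TestForwardBP:
    def test_sbp_exceeds_dbp_across_grid_both_modes(self):
        for r in np.linspace(1.55, 3.6, 9):
            for c in np.linspace(0.30, 0.60, 7):
                p = wk.VesselParams(R=round(r, 4), C=round(c, 4))
                for mode in ("fixed_time", "extremum"):
                    sbp, dbp = wk.forward_bp(p, mode=mode)
                    assert sbp > dbp

    def test_modes_share_dbp_and_sbp_is_close(self):
        """Fixed-time sampling is an approximation of the trace extremum:
        DBP agrees exactly (the trace trough is the end-diastolic value) and
        SBP differs by the documented fixed-time offset (< 10 mmHg, since
        the trace peaks slightly after the 0.14 s sampling time)."""
        for r, c in GRID_SAMPLES:
            p = wk.VesselParams(R=r, C=c)
            s_fix, d_fix = wk.forward_bp(p, mode="fixed_time")
            s_ext, d_ext = wk.forward_bp(p, mode="extremum")
            assert d_ext == pytest.approx(d_fix, abs=1e-6)
            assert s_ext >= s_fix - 1e-9
            assert s_ext - s_fix < 10.0

    def test_sbp_monotone_in_r(self):
        for c in (0.30, 0.45, 0.60):
            sbps = [
                wk.forward_bp(wk.VesselParams(R=r, C=c))[0]
                for r in np.linspace(1.55, 3.6, 15)
            ]
            assert np.all(np.diff(sbps) > 0)

    def test_literal_policy_reproduces_branch_solutions(self):
        p = wk.VesselParams(R=2.0, C=0.45)
        sbp, dbp = wk.forward_bp(p, policy="literal")
        assert sbp == pytest.approx(wk.systolic_pressure(0.14, p), abs=1e-12)
        assert dbp == pytest.approx(wk.diastolic_pressure(0.8, p), abs=1e-12)

    def test_outside_admissible_box_warns(self):
        with pytest.warns(UserWarning, match="admissible"):
            wk.forward_bp(wk.VesselParams(R=1.0, C=0.45))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestDomainTypes:
    def test_timing_invariant(self):
        with pytest.raises(ValueError):
            wk.CardiacTiming(cycle_length=0.8, systole_duration=0.9)

    @pytest.mark.parametrize("kwargs", [{"R": -1, "C": 0.4}, {"R": 2, "C": 0.0}])
    def test_params_positive(self, kwargs):
        with pytest.raises(ValueError):
            wk.VesselParams(**kwargs)

    def test_state_vector_derived_quantities(self):
        p = wk.VesselParams(R=2.0, C=0.5)
        sv = wk.StateVector(V=40.0, lam=0.46)
        assert sv.pressure(p) == pytest.approx(80.0)
        assert sv.flow(p) == pytest.approx(2.0)

    def test_trace_validation_and_text_round_trip(self, tmp_path):
        with pytest.raises(ValueError):
            wk.PressureTrace(times=np.array([0.0, 0.0, 1.0]), pressures=np.zeros(3))
        trace = wk.assemble_cycle(wk.VesselParams(R=2.0, C=0.45)).sample(101)
        path = tmp_path / "trace.tsv"
        trace.to_text(path)
        back = wk.PressureTrace.from_text(path)
        assert back.pressures == pytest.approx(trace.pressures)
        assert back.times == pytest.approx(trace.times)
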