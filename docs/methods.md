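# Methods

## Vessel model

A single arterial segment is represented as a lumped
resistance–compliance–inertance element in the bond-graph sense: a "0"
junction (elastic chamber, state = vascular volume *V*) in series with a
"1" junction (resistive/inertial line, state = pressure momentum
*λ = I·Q*).  The first-order states obey

    dV/dt = Q_in − Q,    dλ/dt = P − P_next − R·Q,
    P = V/C,             Q = λ/I,

which eliminate to the second-order pressure equation

    I·C·P″ + R·C·P′ + P = I·Q_in′ + R·Q_in + P_next.

Constants: inertance *I* = 0.23 mmHg·s²/mL and downstream boundary pressure
*P_next* = 30 mmHg.  The ejection waveform is piecewise sinusoidal over a
0.8 s cycle with a 0.3 s systole: half-sine shoulders on
[0, Ts/4] ∪ [3Ts/4, Ts], a double-frequency mid-systolic bump on
[Ts/4, 3Ts/4], zero in diastole; amplitude 70 in model flow units.  The
flow units are deliberately left model-internal: the waveform's time
integral (≈ 14.7 units/beat) is not calibrated to a physiological stroke
volume, so the model-derived SV/CO carry the same caveat wherever they are
reported.

### Closed-form solutions

The characteristic polynomial I·C·s² + R·C·s + 1 has roots
s± = [−RC ± √(R²C² − 4CI)] / (2CI).  Both always have negative real part
(the element is passive).  Parts of the admissible box have R²C² < 4CI
(e.g. R = 1.55, C = 0.30 gives 0.216 < 0.276), so the complex-conjugate
case is handled throughout via the real damped-oscillation basis.  The
repeated-root locus R²C² = 4CI is measure-zero in the box and raises an
explicit error rather than silently switching to the t·e^{st} form; the
numeric integrator covers it if ever needed.

Each inflow branch contributes a steady particular solution
(constant + sinusoid through the transfer function
H(iω) = 1/(1 − ICω² + iRCω)) plus a two-dimensional homogeneous family.
Three conventions fix the homogeneous coefficients:

* **`matched` (default).**  The mid-systole branch uses unit coefficients
  on both root exponentials (K1 = K2 = 1); the remaining branches are
  continued C¹-continuously forward and backward from it.  The result is a
  single-beat, non-periodic trace.  SBP is defined as the pressure at
  t = 0.14 s (scaled with systole duration) and DBP as the pressure at the
  end of the cycle.  Over the admissible box this convention yields
  SBP ∈ [107, 209] mmHg and DBP ∈ [46, 171] mmHg — the clinically relevant
  range — and it is what the estimation surfaces are built from.
* **`continuity`.**  All eight homogeneous coefficients are solved jointly
  so the trace is C¹ at every breakpoint *and* cycle-periodic: the exact
  steady state of the periodically driven ODE.  It matches the RK4 oracle
  to < 1e−3 mmHg and anchors the correctness tests.
* **`literal`.**  The fixed default coefficients (K1 = K2 = 1,
  K3 = −200, K4 = −400) evaluated directly in the branch formulas.
  Retained for fidelity: with negative coefficients on decaying
  exponentials the diastolic branch is negative and *increasing* toward
  P_next (≈ −41 mmHg at t = 0.8 s mid-box), which is not a usable
  diastolic pressure; the convention exists to reproduce the historical
  formulas, not to build surfaces.

Why `matched` is the default and not `continuity`: any cycle-periodic
solution must satisfy mean(P) = P_next + R·mean(Q_in) (integrate the state
equations over one period), which with amplitude-70 inflow caps the
periodic SBP at ≈ 113 mmHg over the admissible box.  Clinical pressures
(120/70, heart-failure baselines of 118–161 mmHg) are therefore *only*
representable by the single-beat construction, whose systolic plateau
tracks the quasi-steady forcing level R·Q̄_sys + P_next.  The `matched`
convention is exactly that: the literal mid-systolic solution with its
transient continued consistently through the rest of the beat.

Two fixed-time conventions deserve comment.  First, SBP is *defined* at
t = 0.14 s although the mid-systolic branch actually peaks near
t ≈ 0.224 s for all admissible (R, C); the peak is strictly interior to
the branch (a tested property) and the fixed-time value sits 4–7 mmHg
below it (`extremum` mode reports the true trace extrema; the offset is
a documented approximation, not an error).  Second, in `extremum` mode
the trace minimum coincides with the end-of-cycle value, so both modes
agree exactly on DBP.

### Numeric oracle

`solve_ode_numeric` integrates the first-order system with classical
fixed-step RK4 (2000 steps/cycle), cycle by cycle, declaring steady state
when the successive-cycle max-abs pressure difference falls below
1e−4 mmHg.  It warm-starts at the analytic mean pressure
P_next + R·mean(Q_in) to shorten the transient.  The oracle shares no code
path with the closed forms (it never touches the characteristic roots or
particular solutions) and is the independent reference for the `continuity`
assembly.

## Inverse estimation

Surfaces: `forward_bp` is tabulated on a 201×201 grid over
[1.55, 3.60] × [0.30, 0.60] (one sweep produces both the SBP and DBP
surface; pairs are cached in-process keyed by grid, mode, policy, I,
P_next, timing and amplitude, and exportable as self-describing JSON).
The surface geometry makes the inverse problem well-posed: SBP rises
steeply and almost exclusively with R (≈ 50 mmHg per unit R), while DBP
rises with both R and C, so the two iso-contours cross transversally.
Monotonicity of SBP in R is asserted at test time; a violation would
downgrade the estimate status rather than silently picking a crossing.

Contours are extracted by marching squares with linear edge interpolation
(scikit-image); crossings by exact 2-D segment intersection (shapely).  A
unique crossing yields status `unique`; several crossings are all reported
(`multiple`) with the primary chosen nearest the brute-force argmin —
the uniqueness assumption is surfaced, never hidden.  The crossing is
refined by two Newton steps on the exact forward model
(finite-difference Jacobian), which drives round-trip residuals to
floating-point noise; estimates within one cell of the box edge carry a
`boundary` flag.  Degenerate inputs: SBP ≤ DBP is rejected; pressures
outside the surface range return a `none`-status estimate with
diagnostics instead of raising.

The test oracle `brute_force_rc` minimizes
(SBP_model − sbp)² + (DBP_model − dbp)² exhaustively: over every surface
node, then over a 4×-denser sub-grid of direct forward evaluations in a
±3-cell window around the coarse argmin.  The refinement stage exists
because the objective valley is anisotropic — SBP changes ≈ 0.5 mmHg per
R-cell but DBP only ≈ 0.1 mmHg per C-cell — so a node-limited argmin can
drift a few C-cells along the nearly flat valley; refining pushes the
oracle's quantization error well below one surface cell, making the
one-cell agreement check a test of the estimator rather than of the
oracle's grid.

## Dose–effect modelling

Treatment effects are the fractional parameter changes
ΔR = (R_post − R_pre)/R_pre, ΔC = (C_post − C_pre)/C_pre, obtained by
inverting the pressure model before and after treatment.  Sequential
treatments compose multiplicatively, R·(1 + Δ₁)(1 + Δ₂) — a tested
invariant.  The per-drug dose dependence is fitted by least squares with
the zero-anchored rectangular hyperbola E(d) = E_max·d/(d50 + d): ACE
binding saturates, so fractional change plateaus at E_max (dimensionless)
with half-maximal effect at d50 (mg/day).  The form guarantees E(0) = 0,
monotonicity and |E(d)| ≤ |E_max|.  Fits are weighted by group size when
every record carries one; at least three distinct doses are required.
`apply_dose` maps a baseline through the fitted curves,
X_post = X_base·(1 + E(d)), clamping to the admissible box with a warning.

## Cardiac integrated index

CII = Σᵢ yᵢ·wᵢ over (MAP, PP, HR, CO, SV, EF, SW) with fixed weights
(0.2333, 0.3084, 0.0415, −0.3737, −0.3678, −0.3566, 0.3266).  The sum acts
on **raw** component values in their conventional units (mmHg, mmHg,
beats/min, L/min, mL, %, J/beat) — the packaged worked-example arithmetic
confirms raw rather than standardized components — so the score is not
invariant to unit changes; this is reproduced literally and documented
rather than "fixed".  Weight signs give the clinical reading: pressure
loads and stroke work raise the score, pump performance (CO, SV, EF)
lowers it; lower CII = better cardiac state.  `profile_from_model`
supplies the components a one-segment model can produce (MAP as trace
time-average, PP = SBP − DBP, HR = 60/cycle, SV as the inflow integral in
model units, CO = SV·HR/1000); EF and SW cannot come from a one-segment
vessel and are mandatory user supplements, with HR overridable by a
clinical measurement (the nominal 60/0.8 = 75 beats/min is a cycle-length
artifact, not a patient datum).

## Synthetic cohort generator

The generator emulates the grouped-trial setting used for dose-effect
fitting: `n_patients` = 200 by default, (R, C) drawn uniformly from
R ∈ [2.3, 3.2], C ∈ [0.34, 0.45] — a heart-failure-like interior of the
admissible box chosen so every post-treatment parameter stays inside the
box for every drug/dose level — doses assigned from the clinical ladder
{1.25, 2.5, 5, 10, 20, 40} mg/day, pre/post pressures computed with the
forward model under ground-truth Emax curves, and iid Gaussian noise
(sd 2 mmHg) added to all four pressures.  Draws whose noisy pressures
become unreachable are redrawn and counted.  Ground-truth curves for the
two reference ACEIs: enalapril E_max(ΔR) = −0.28, E_max(ΔC) = +0.10,
d50 = 12 mg/d (gradual, resistance-dominated); lisinopril
E_max(ΔR) = −0.30, E_max(ΔC) = +0.28, d50 = 1 mg/d (sharp, ≈ 95% of
asymptote by 19–20 mg/d, resistance and compliance effects of comparable
size).  These were fixed once as qualitatively realistic values; they are
study conditions, not tuning knobs.

What the generator does *not* emulate: real trial records are group means
over 19–148 patients (with correspondingly small standard errors), therapy
durations differ between trials, and individual drug response varies;
the generator produces single-patient records with homogeneous response.
Passing recovery tests therefore demonstrate that the
estimate→delta→fit pipeline is unbiased and correctly propagates
measurement noise — not that 2 mmHg single-reading noise suffices to pin
every pharmacodynamic parameter.

### Known limitation: power of the small-effect curve

With per-patient noise of 2 mmHg on four pressures, the estimator-propagated
noise on a single record's ΔC is several percent absolute.  For the
enalapril compliance curve (|E_max| = 0.10) the resulting sampling error on
the fitted E_max is ≈ 13–15% (measured across seeds) — above the 10%
recovery tolerance the acceptance suite asserts.  The corresponding
acceptance sub-check fails for that one curve and is left failing: the
limit is statistical power under the stated study conditions, not an
estimator or fitting defect (the three well-identified curves recover
within ≈ 5% / ≈ 12%, and point-level fits with σ = 0.01 delta noise
recover E_max within 10% as tested in the dose module).

## Numerical choices

* Homogeneous bases are evaluated at branch-relative time offsets so the
  fast-root exponential never underflows the assembly matrices.
* Surface default 201×201 with bilinear interpolation; contour points
  re-interpolate to the target within 1e−6 mmHg.
* Newton polish: 2 iterations, central differences with steps of 1e−5 of
  the box span, iterates clipped to the box.
* RK4: 2000 steps/cycle (≥ 1000 enforced), steady-state tolerance
  1e−4 mmHg, hard cap 200 cycles.
* FD residual oracle in the tests: 5-point 4th-order stencils with
  h = 5e−4 s, giving residual resolution ≈ 1e−7 relative — comfortably
  below the 1e−6 assertion.
* Report formatting: pressures 1 dp, R/C 4 dp, CII 2 dp.
* Determinism: surfaces, contours, intersections and polishing are all
  deterministic; fixed generator seeds reproduce cohorts byte-identically.

## Problem sizes used by the test and acceptance runs

Closed-form-vs-oracle agreement is checked on 20 grid points (5×4 over the
box); inverse round trips on 100 seeded draws plus 25 oracle-equivalence
pairs; dose-curve recovery on one 200-patient two-drug cohort; the
saturation shape check on a 60-patient noiseless cohort.  These sizes keep
the full suite under half a minute on one CPU while leaving the stochastic
checks well-powered for the quantities they assert.
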