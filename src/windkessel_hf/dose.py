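"""ACE-inhibitor dose-effect modelling on vascular resistance and compliance.

Treatment effect is summarized as fractional changes of the Windkessel
parameters, dR = (R_post - R_pre)/R_pre and dC = (C_post - C_pre)/C_pre,
obtained by inverting the pressure model before and after treatment.  The
per-drug dose-effect relationship is fitted as a zero-anchored rectangular
hyperbola (Emax model),

    E(d) = E_max * d / (d50 + d),

the standard saturating pharmacodynamic form: ACE binding saturates, so the
fractional parameter change plateaus at E_max with half-maximal effect at
dose d50 (mg/day).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, InsufficientDataError
from .estimator import ParameterGrid, estimate_rc
from .waveform import ADMISSIBLE_C, ADMISSIBLE_R

__all__ = [
    "TreatmentRecord",
    "DeltaRC",
    "DoseEffectCurve",
    "delta_r",
    "delta_c",
    "deltas_from_record",
    "fit_dose_points",
    "fit_dose_curve",
    "apply_dose",
]


@dataclass(frozen=True)
class TreatmentRecord:
    """One treatment group: drug, daily dose and pre/post pressures (mmHg)."""

    drug: str
    dose: float  # mg/day
    sbp_pre: float
    dbp_pre: float
    sbp_post: float
    dbp_post: float
    group_size: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sbp_pre > self.dbp_pre:
            raise ValueError("sbp_pre must exceed dbp_pre")
        if not self.sbp_post > self.dbp_post:
            raise ValueError("sbp_post must exceed dbp_post")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class DeltaRC:
    """Fractional treatment-induced changes of R and C (dimensionless)."""

    delta_r: float
    delta_c: float
    status_pre: str = "unique"
    status_post: str = "unique"

    def __post_init__(self) -> None:
        for name in ("delta_r", "delta_c"):
            v = getattr(self, name)
            if np.isfinite(v) and v <= -1.0:
                raise ValueError(f"{name} must exceed -1 (post value must stay positive)")

    @property
    def ok(self) -> bool:
        return self.status_pre == "unique" and self.status_post == "unique"


@dataclass(frozen=True)
class DoseEffectCurve:
    """Fitted saturating dose-effect curve for one drug and one quantity."""

    drug: str
    quantity: str  # "delta_r" | "delta_c"
    e_max: float
    d50: float  # mg/day
    fit_rss: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.d50 <= 0:
            raise ValueError("d50 must be > 0")

    def __call__(self, dose):
        dose = np.asarray(dose, dtype=float)
        out = self.e_max * dose / (self.d50 + dose)
        return out if out.ndim else float(out)

    def saturation_dose(self, fraction: float = 0.95) -> float:
        """Dose at which the curve reaches ``fraction`` of E_max."""
        return self.d50 * fraction / (1.0 - fraction)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "drug": self.drug, "quantity": self.quantity,
                    "e_max": self.e_max, "d50_mg_d": self.d50,
                    "fit_rss": self.fit_rss, "n_points": self.n_points,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "DoseEffectCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            drug=d["drug"], quantity=d["quantity"], e_max=d["e_max"],
            d50=d["d50_mg_d"], fit_rss=d["fit_rss"], n_points=d["n_points"],
        )


def delta_r(r_pre: float, r_post: float) -> float:
    """Fractional resistance change (R_post - R_pre) / R_pre."""
    if not r_pre > 0:
        raise ValueError(f"R_pre must be > 0, got {r_pre}")
    return (r_post - r_pre) / r_pre


def delta_c(c_pre: float, c_post: float) -> float:
    """Fractional compliance change (C_post - C_pre) / C_pre."""
    if not c_pre > 0:
        raise ValueError(f"C_pre must be > 0, got {c_pre}")
    return (c_post - c_pre) / c_pre


def deltas_from_record(
    rec: TreatmentRecord,
    grid: ParameterGrid | None = None,
    bp_mode: str = "fixed_time",
    policy: str = "matched",
) -> DeltaRC:
    """Invert pre/post pressures to (R, C) and form the fractional changes.

    Estimator failures are propagated as flagged statuses (with NaN deltas
    when either inversion fails), never silently dropped.
    """
    pre = estimate_rc(rec.sbp_pre, rec.dbp_pre, grid, bp_mode, policy)
    post = estimate_rc(rec.sbp_post, rec.dbp_post, grid, bp_mode, policy)
    if pre.status == "none" or post.status == "none":
        return DeltaRC(
            delta_r=float("nan"), delta_c=float("nan"),
            status_pre=pre.status, status_post=post.status,
        )
    return DeltaRC(
        delta_r=delta_r(pre.R, post.R),
        delta_c=delta_c(pre.C, post.C),
        status_pre=pre.status,
        status_post=post.status,
    )


def _emax_model(d, e_max, d50):
    return e_max * d / (d50 + d)


def fit_dose_points(
    doses,
    deltas,
    quantity: str,
    drug: str = "",
    weights=None,
) -> DoseEffectCurve:
    """Least-squares Emax fit to (dose, delta) points.

    ``weights`` are group sizes; the fit minimizes the group-size-weighted
    residual sum of squares when provided.  Requires >= 3 distinct doses
    (two parameters plus one degree of freedom).
    """
    doses = np.asarray(doses, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    keep = np.isfinite(deltas)
    doses, deltas = doses[keep], deltas[keep]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[keep]
    if len(np.unique(doses)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct doses to fit an Emax curve, got {len(np.unique(doses))}"
        )
    span = float(np.max(np.abs(deltas)))
    e0 = deltas[np.argmax(doses)] if span > 0 else 0.0
    d0 = float(np.median(doses[doses > 0])) if np.any(doses > 0) else 1.0
    sigma = None if weights is None else 1.0 / np.sqrt(weights)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat-data fits have singular covariance
            popt, _ = curve_fit(
                _emax_model, doses, deltas,
                p0=[e0 if e0 != 0 else 1e-6, d0],
                sigma=sigma,
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        raise FitError(f"Emax fit failed for drug={drug!r}, quantity={quantity}: {exc}") from exc
    resid = deltas - _emax_model(doses, *popt)
    rss = float(np.sum(resid**2 if weights is None else weights * resid**2))
    return DoseEffectCurve(
        drug=drug, quantity=quantity,
        e_max=float(popt[0]), d50=float(popt[1]),
        fit_rss=rss, n_points=len(doses),
    )


def fit_dose_curve(
    records: list[TreatmentRecord],
    quantity: str,
    grid: ParameterGrid | None = None,
    bp_mode: str = "fixed_time",
    policy: str = "matched",
) -> DoseEffectCurve:
    """Fit the per-drug dose-effect curve from grouped pre/post pressures.

    Each record is inverted with :func:`deltas_from_record`; the fit is
    weighted by ``group_size`` when every record provides one.
    """
    if quantity not in ("delta_r", "delta_c"):
        raise ValueError("quantity must be 'delta_r' or 'delta_c'")
    drugs = {rec.drug for rec in records}
    if len(drugs) != 1:
        raise ValueError(f"records must belong to a single drug, got {sorted(drugs)}")
    doses, values, sizes = [], [], []
    for rec in records:
        d = deltas_from_record(rec, grid, bp_mode, policy)
        doses.append(rec.dose)
        values.append(getattr(d, quantity) if d.ok else float("nan"))
        sizes.append(rec.group_size)
    weights = sizes if all(s is not None for s in sizes) else None
    return fit_dose_points(doses, values, quantity, drug=drugs.pop(), weights=weights)


def apply_dose(
    r_base: float,
    c_base: float,
    curve_r: DoseEffectCurve,
    curve_c: DoseEffectCurve,
    dose: float,
) -> tuple[float, float]:
    """Apply a dose to baseline (R, C): X_post = X_base * (1 + curve(dose)).

    Results falling outside the admissible box are clamped with a warning;
    a non-positive result is a model error.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if not (r_base > 0 and c_base > 0):
        raise ValueError("baseline R and C must be > 0")
    r_post = r_base * (1.0 + curve_r(dose))
    c_post = c_base * (1.0 + curve_c(dose))
    if r_post <= 0 or c_post <= 0:
        raise ValueError(
            f"dose {dose} mg/d drives parameters non-positive (R={r_post}, C={c_post})"
        )
    clamped_r = min(max(r_post, ADMISSIBLE_R[0]), ADMISSIBLE_R[1])
    clamped_c = min(max(c_post, ADMISSIBLE_C[0]), ADMISSIBLE_C[1])
    if clamped_r != r_post or clamped_c != c_post:
        warnings.warn(
            f"post-treatment parameters (R={r_post:.4f}, C={c_post:.4f}) clamped to "
            f"the admissible box {ADMISSIBLE_R} x {ADMISSIBLE_C}",
            stacklevel=2,
        )
    return clamped_r, clamped_c
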