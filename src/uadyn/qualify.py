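"""Model qualification procedures on independent cohorts.

Two procedures mirror how the disposition model is checked against data it
was not trained on:

* **Renal impairment.**  Baseline fractional excretion and production rate
  are interpolated against GFR with a nonlinear (exponential) regression
  per study; the interpolated baselines plus a spline through each
  subject's observed uricosuric concentrations drive a 24-h simulation,
  from which relative changes of serum and urine uric acid are computed.
* **Hyperuricemic patients (Phase-III-style).**  For each retained subject
  the on-treatment serum concentration is predicted from the steady-state
  relation at the measured on-treatment fractional excretion, and compared
  with the observed relative change from baseline.  Subjects on background
  allopurinol get the oxypurinol-exposure correction (lesinurad lowers the
  daily-average oxypurinol concentration, partially undoing the production
  inhibition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import ML_MIN_TO_L_H, MG_DL_TO_MG_L, PhysiologyState
from .drugs import (
    DRUG_LIBRARY,
    ProductionInhibitorParams,
    ReabsorptionInhibitorParams,
    corrected_relative_change,
    interpolate_observed_concentrations,
    oxypurinol_interaction_factor,
)
from .simulate import RelativeChange24h, SimulationPlan, relative_change_24h, run_simulation

__all__ = [
    "GfrInterpolation",
    "Phase3Subject",
    "fit_gfr_interpolation",
    "predict_renal_subject",
    "filter_phase3_subjects",
    "predict_phase3_change",
    "DEFAULT_OXYPURINOL_BACKGROUND_NG_ML",
    "DEFAULT_OXYPURINOL_REDUCTION",
]

# Daily-average oxypurinol exposure on 300 mg allopurinol, and the
# fractional reduction of that exposure caused by co-administered lesinurad.
DEFAULT_OXYPURINOL_BACKGROUND_NG_ML = 10_000.0
DEFAULT_OXYPURINOL_REDUCTION = 0.32


@dataclass(frozen=True)
class GfrInterpolation:
    """Baseline parameter as a function of GFR (mL/min).

    ``form`` is ``"constant"`` (coef = (c,)) or ``"exponential"``
    (coef = (alpha, beta, gamma) for ``alpha + beta * exp(gamma * gfr)``).
    Evaluation is restricted to the GFR range the regression was fitted on
    (extrapolating a fitted exponential is not meaningful).
    """

    target: str  # "fe0" or "kp0"
    form: str
    coef: tuple[float, ...]
    gfr_range: tuple[float, float]

    def __call__(self, gfr_ml_min: float) -> float:
        lo, hi = self.gfr_range
        if not lo - 1e-9 <= gfr_ml_min <= hi + 1e-9:
            raise ValueError(
                f"GFR {gfr_ml_min} outside fitted range [{lo}, {hi}] for {self.target}"
            )
        if self.form == "constant":
            return self.coef[0]
        alpha, beta, gamma = self.coef
        return alpha + beta * math.exp(gamma * gfr_ml_min)


def _fit_one_interpolation(gfr, values, target) -> GfrInterpolation:
    gfr = np.asarray(gfr, float)
    values = np.asarray(values, float)
    rng = (float(gfr.min()), float(gfr.max()))
    const = float(values.mean())
    sse_const = float(np.sum((values - const) ** 2))
    best = None
    for gamma0 in (-0.05, 0.05):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda g, a, b, c: a + b * np.exp(c * g),
                    gfr,
                    values,
                    p0=(const, values[np.argmin(gfr)] - const, gamma0),
                    maxfev=20000,
                )
            pred = popt[0] + popt[1] * np.exp(popt[2] * gfr)
            sse = float(np.sum((values - pred) ** 2))
            if np.all(np.isfinite(popt)) and (best is None or sse < best[1]):
                best = (popt, sse)
        except (RuntimeError, ValueError):
            continue
    # Exponential must improve the fit by more than 1% of the constant SSE
    # (beyond numerical noise), otherwise the parameter is declared
    # GFR-independent.
    floor = 1e-12 * float(np.sum(values**2))
    if best is not None and sse_const - best[1] > 0.01 * sse_const + floor:
        return GfrInterpolation(target, "exponential", tuple(map(float, best[0])), rng)
    if best is None:
        warnings.warn(
            f"exponential interpolation of {target} vs GFR degenerate; "
            "falling back to constant",
            stacklevel=3,
        )
    return GfrInterpolation(target, "constant", (const,), rng)


def fit_gfr_interpolation(
    gfr_ml_min, fe0_values, kp0_values
) -> tuple[GfrInterpolation, GfrInterpolation]:
    """Least-squares interpolation of (fe0, kp0) versus GFR across subjects.

    Each target is fitted with ``alpha + beta*exp(gamma*gfr)``; when the
    exponential does not improve the residual sum of squares by more than
    1% over a constant, the constant is selected.
    """
    gfr = np.asarray(gfr_ml_min, float)
    if gfr.size < 4:
        raise ValueError("need >= 4 subjects spanning a GFR range")
    if np.ptp(gfr) <= 0:
        raise ValueError("subjects must span a GFR range")
    fe0_i = _fit_one_interpolation(gfr, fe0_values, "fe0")
    kp0_i = _fit_one_interpolation(gfr, kp0_values, "kp0")
    return fe0_i, kp0_i


def predict_renal_subject(
    gfr_ml_min: float,
    fe0_interp: GfrInterpolation,
    kp0_interp: GfrInterpolation,
    conc_times,
    conc_values,
    rin_params: ReabsorptionInhibitorParams,
    *,
    cl_i: float = 0.27,
    v_ua: float = 19.0,
) -> RelativeChange24h:
    """Predicted 24-h relative changes for one renally impaired subject.

    The subject's baseline physiology is taken from the GFR interpolations,
    the uricosuric exposure from a spline through the observed plasma
    concentrations (which must span 24 h), and the system is simulated for
    24 h from its predose steady state.
    """
    fe0 = fe0_interp(gfr_ml_min)
    kp0 = kp0_interp(gfr_ml_min)
    if not 0 < fe0 < 1:
        raise ValueError(f"interpolated fe0 {fe0} outside (0, 1)")
    if kp0 <= 0:
        raise ValueError(f"interpolated kp0 {kp0} must be > 0")
    phys = PhysiologyState(
        gfr=gfr_ml_min * ML_MIN_TO_L_H, fe0=fe0, kp0=kp0, v_ua=v_ua, cl_i=cl_i
    )
    profile = interpolate_observed_concentrations(conc_times, conc_values)
    plan = SimulationPlan(
        phys=phys, rin=(profile, rin_params), horizon=24.0, dt=0.05
    )
    result = run_simulation(plan)
    return relative_change_24h(result, phys)


@dataclass
class Phase3Subject:
    """One hyperuricemic patient's baseline and on-treatment summaries.

    Concentrations in clinical mg/dL, GFR in mL/min.  ``sua_on_mg_dl`` is
    the mean of the available monthly on-treatment serum values;
    ``fe_on`` the measured on-treatment fractional excretion.
    """

    subject_id: str
    sua_base_mg_dl: float | None
    gfr_ml_min: float | None
    fe0: float | None
    fe_on: float | None
    sua_on_mg_dl: float | None
    on_allopurinol: bool = False

    def complete(self) -> bool:
        return all(
            v is not None and np.isfinite(v) and v > 0
            for v in (
                self.sua_base_mg_dl,
                self.gfr_ml_min,
                self.fe0,
                self.fe_on,
                self.sua_on_mg_dl,
            )
        )

    def observed_change(self) -> float:
        return self.sua_on_mg_dl / self.sua_base_mg_dl - 1.0


def filter_phase3_subjects(
    subjects: Sequence[Phase3Subject],
) -> tuple[list[Phase3Subject], dict[str, int]]:
    """Retain subjects whose response is physiologically interpretable.

    Kept: serum uric acid decreased from baseline (proxy for treatment
    compliance) AND fractional excretion increased (proxy against
    measurement error).  Returns (retained, exclusion counts by reason).
    """
    retained = []
    exclusions = {"incomplete": 0, "serum_not_decreased": 0, "fe_not_increased": 0}
    for s in subjects:
        if not s.complete():
            exclusions["incomplete"] += 1
        elif not s.sua_on_mg_dl < s.sua_base_mg_dl:
            exclusions["serum_not_decreased"] += 1
        elif not s.fe_on > s.fe0:
            exclusions["fe_not_increased"] += 1
        else:
            retained.append(s)
    return retained, exclusions


def predict_phase3_change(
    subject: Phase3Subject,
    *,
    cl_i: float = 0.27,
    pin_params: ProductionInhibitorParams | None = None,
    oxypurinol_conc_ng_ml: float = DEFAULT_OXYPURINOL_BACKGROUND_NG_ML,
    reduction: float = DEFAULT_OXYPURINOL_REDUCTION,
) -> float:
    """Predicted relative change in serum uric acid for one subject.

    The baseline production rate follows from the subject's baseline
    concentration, GFR and fe0; the on-treatment concentration from the
    steady-state relation at the measured on-treatment fractional
    excretion.  The baseline concentration cancels, so the prediction is

        delta = (cl_i + gfr*fe0) / (cl_i + gfr*fe_on) - 1.

    For subjects on background allopurinol the oxypurinol-exposure
    correction is applied (co-administered lesinurad lowers daily-average
    oxypurinol by ``reduction``, inflating the achievable serum level).
    """
    if not subject.complete():
        raise ValueError(f"subject {subject.subject_id!r} has missing fields")
    gfr = subject.gfr_ml_min * ML_MIN_TO_L_H
    conc_base = subject.sua_base_mg_dl * MG_DL_TO_MG_L
    kp = conc_base * (cl_i + gfr * subject.fe0)
    conc_on = kp / (cl_i + gfr * subject.fe_on)
    delta = conc_on / conc_base - 1.0
    if subject.on_allopurinol:
        if pin_params is None:
            pin_params = DRUG_LIBRARY["oxypurinol"].params()
        factor = oxypurinol_interaction_factor(
            oxypurinol_conc_ng_ml, pin_params, reduction
        )
        delta = corrected_relative_change(delta, factor)
    return delta
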