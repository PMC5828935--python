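"""State equations of whole-body uric acid disposition.

The model tracks the amount of uric acid in a single, well-mixed serum
compartment.  Uric acid enters by metabolic production (rate ``kp``, mg/h)
and leaves by two parallel first-order routes: intestinal secretion
(clearance ``cl_i``, L/h) and renal excretion.  The kidney filters serum
urate at the glomerular filtration rate (GFR); the proximal tubule
reabsorbs most of the filtered load and the fraction that escapes
reabsorption and appears in urine is the fractional excretion coefficient
``fe``.  Renal urate clearance is therefore ``gfr * fe`` and the serum
balance reads

    dS/dt = kp - cl_i * [S] - gfr * fe * [S],        [S] = S / v_ua
    dU/dt = gfr * fe * [S]

with ``S`` the amount in serum (mg), ``U`` the cumulative amount excreted
in urine (mg) and ``v_ua`` the volume of distribution (L).

All quantities are kept in a fixed internal unit system -- mg, L, h --
and converted only at I/O boundaries (clinical serum urate is reported in
mg/dL, creatinine clearance in mL/min).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "PhysiologyState",
    "UAState",
    "SteadyState",
    "ua_derivatives",
    "steady_state",
    "baseline_production_rate",
    "baseline_fractional_excretion",
    "convert_units",
    "cockcroft_gault",
    "ML_MIN_TO_L_H",
    "MG_DL_TO_MG_L",
]

ML_MIN_TO_L_H = 0.06
MG_DL_TO_MG_L = 10.0

_UNIT_FACTORS = {
    ("mg/dL", "mg/L"): 10.0,
    ("mg/L", "mg/dL"): 0.1,
    ("mL/min", "L/h"): 0.06,
    ("L/h", "mL/min"): 1.0 / 0.06,
    ("mg/h", "mg/24h"): 24.0,
    ("mg/24h", "mg/h"): 1.0 / 24.0,
}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact factor conversion between the unit pairs used at I/O boundaries.

    Supported pairs: mg/dL <-> mg/L, mL/min <-> L/h, mg/h <-> mg/24h, and
    the identity conversion.  Anything else raises ``ValueError``.
    """
    if from_unit == to_unit:
        return value
    try:
        factor = _UNIT_FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise ValueError(
            f"unsupported unit conversion: {from_unit!r} -> {to_unit!r}"
        ) from None
    return value * factor


def cockcroft_gault(
    age_years: float, weight_kg: float, serum_creatinine_mg_dl: float, sex: str
) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min), actual body weight.

    CrCl = (140 - age) * weight / (72 * SCr), multiplied by 0.85 for women.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if age_years >= 140:
        raise ValueError("age >= 140 years gives a non-positive clearance")
    for name, val in (
        ("age_years", age_years),
        ("weight_kg", weight_kg),
        ("serum_creatinine_mg_dl", serum_creatinine_mg_dl),
    ):
        if not val > 0 or not math.isfinite(val):
            raise ValueError(f"{name} must be positive and finite, got {val}")
    crcl = (140.0 - age_years) * weight_kg / (72.0 * serum_creatinine_mg_dl)
    if sex == "female":
        crcl *= 0.85
    return crcl


def _check_positive_finite(obj, fields) -> None:
    for name in fields:
        val = getattr(obj, name)
        if not math.isfinite(val):
            raise ValueError(f"{type(obj).__name__}.{name} is not finite: {val}")
        if not val > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {val}")


@dataclass(frozen=True)
class PhysiologyState:
    """A subject's (or group's) uric acid disposition parameters.

    Parameters
    ----------
    gfr : float
        Glomerular filtration rate, L/h (clinical mL/min x 0.06).
    fe0 : float
        Baseline fractional excretion coefficient, in (0, 1].
    kp0 : float
        Baseline uric acid production rate, mg/h.
    v_ua : float
        Volume of distribution of uric acid, L.
    cl_i : float
        Intestinal clearance of uric acid, L/h.
    s_ua_base : float, optional
        Baseline serum uric acid concentration, mg/L.  When omitted it is
        derived from the drug-free steady state ``kp0 / (cl_i + gfr*fe0)``.
    """

    gfr: float
    fe0: float
    kp0: float
    v_ua: float = 19.0
    cl_i: float = 0.27
    s_ua_base: float | None = None

    def __post_init__(self) -> None:
        _check_positive_finite(self, ("gfr", "fe0", "kp0", "v_ua", "cl_i"))
        if self.fe0 > 1:
            raise ValueError(f"fe0 must be <= 1, got {self.fe0}")
        if self.s_ua_base is None:
            conc = self.kp0 / (self.cl_i + self.gfr * self.fe0)
            object.__setattr__(self, "s_ua_base", conc)
        _check_positive_finite(self, ("s_ua_base",))

    @classmethod
    def from_clinical(
        cls,
        *,
        gfr_ml_min: float,
        fe0: float,
        sua_mg_dl: float,
        v_ua: float = 19.0,
        cl_i: float = 0.27,
    ) -> "PhysiologyState":
        """Build a state from clinical units, back-calculating ``kp0``.

        The production rate is obtained from the steady-state mass balance
        (baseline concentration and urinary excretion rate consistent with
        ``fe0`` and GFR), so the returned state is exactly at steady state
        at the stated baseline concentration.
        """
        gfr = gfr_ml_min * ML_MIN_TO_L_H
        conc = sua_mg_dl * MG_DL_TO_MG_L
        x_ua = conc * gfr * fe0
        kp0 = baseline_production_rate(conc, x_ua, cl_i)
        return cls(gfr=gfr, fe0=fe0, kp0=kp0, v_ua=v_ua, cl_i=cl_i, s_ua_base=conc)


@dataclass
class UAState:
    """Instantaneous simulation state: serum amount, cumulative urine, time."""

    s_ua: float  # mg in serum compartment
    u_ua: float = 0.0  # mg excreted in urine since the last collection reset
    t: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.s_ua < 0:
            raise ValueError(f"UAState.s_ua must be >= 0, got {self.s_ua}")
        if self.u_ua < 0:
            raise ValueError(f"UAState.u_ua must be >= 0, got {self.u_ua}")


@dataclass(frozen=True)
class SteadyState:
    """Drug-free or on-drug steady state of the disposition system."""

    conc: float  # serum uric acid concentration, mg/L
    x_ua: float  # urinary excretion rate, mg/h
    cl_total: float  # total clearance cl_i + gfr*fe, L/h


def ua_derivatives(
    state: UAState, kp: float, fe: float, phys: PhysiologyState
) -> tuple[float, float]:
    """Rates of change (dS/dt, dU/dt) in mg/h for the serum/urine balance."""
    for name, val in (("kp", kp), ("fe", fe), ("s_ua", state.s_ua)):
        if not math.isfinite(val):
            raise ValueError(f"non-finite {name}: {val}")
    if kp < 0:
        raise ValueError(f"kp must be >= 0, got {kp}")
    if not 0 <= fe <= 1:
        raise ValueError(f"fe must be in [0, 1], got {fe}")
    conc = state.s_ua / phys.v_ua
    renal = phys.gfr * fe * conc
    ds_dt = kp - phys.cl_i * conc - renal
    return ds_dt, renal


def steady_state(
    phys: PhysiologyState, kp: float | None = None, fe: float | None = None
) -> SteadyState:
    """Analytic steady state for production rate ``kp`` and excretion ``fe``.

    Defaults to the drug-free baseline (``kp0``, ``fe0``) of ``phys``.
    """
    kp = phys.kp0 if kp is None else kp
    fe = phys.fe0 if fe is None else fe
    if kp < 0:
        raise ValueError(f"kp must be >= 0, got {kp}")
    cl_total = phys.cl_i + phys.gfr * fe
    if cl_total <= 0:
        if kp > 0:
            raise ValueError("zero total clearance with kp > 0: no finite steady state")
        return SteadyState(conc=0.0, x_ua=0.0, cl_total=cl_total)
    conc = kp / cl_total
    x_ua = kp * phys.gfr * fe / cl_total
    return SteadyState(conc=conc, x_ua=x_ua, cl_total=cl_total)


def baseline_production_rate(conc: float, x_ua: float, cl_i: float) -> float:
    """Back-calculate the baseline production rate from steady-state data.

    ``kp0 = [S] * cl_i + x_ua`` -- the intestinal elimination rate plus the
    urinary excretion rate, both measured without urate-lowering treatment.
    """
    for name, val in (("conc", conc), ("x_ua", x_ua), ("cl_i", cl_i)):
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")
    return conc * cl_i + x_ua


def baseline_fractional_excretion(conc: float, x_ua: float, gfr: float) -> float:
    """Back-calculate baseline fractional excretion: ``fe0 = x_ua / ([S]*gfr)``.

    Measured data can occasionally produce ``fe0 > 1``; this is reported with
    a warning rather than rejected, and downstream fitting clamps at 1.
    """
    if conc <= 0:
        raise ValueError(f"conc must be > 0 to compute fe0, got {conc}")
    if gfr <= 0:
        raise ValueError(f"gfr must be > 0 to compute fe0, got {gfr}")
    if x_ua < 0:
        raise ValueError(f"x_ua must be >= 0, got {x_ua}")
    fe0 = x_ua / (conc * gfr)
    if fe0 > 1:
        warnings.warn(
            f"computed fractional excretion {fe0:.3f} > 1 (noisy inputs?)",
            stacklevel=2,
        )
    return fe0
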