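"""Drug-effect models and plasma concentration profiles.

Two saturable (Emax-type) effect models map plasma drug concentration to
the parameters of the uric acid disposition system:

* production inhibitors (xanthine oxidase inhibitors: the allopurinol
  metabolite oxypurinol, and febuxostat) multiply the production rate:
  ``kp = kp0 * (1 - r_max * C / (C + p50))``;
* reabsorption inhibitors (uricosurics such as lesinurad) add to the
  fractional excretion coefficient:
  ``fe = fe0 + f_max * C / (C + p50)``.

Concentration inputs are plasma concentrations in ng/mL and are provided
through :class:`ConcentrationProfile` objects -- either a simulated
one-compartment oral-absorption model with dose superposition, or a cubic
spline through observed concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "ProductionInhibitorParams",
    "ReabsorptionInhibitorParams",
    "ConcentrationProfile",
    "StandInPKParams",
    "DrugSpec",
    "DRUG_LIBRARY",
    "production_rate_under_drug",
    "fe_under_drug",
    "max_fractional_excretion",
    "oxypurinol_interaction_factor",
    "corrected_relative_change",
    "standin_pk_profile",
    "interpolate_observed_concentrations",
    "constant_profile",
]


@dataclass(frozen=True)
class ProductionInhibitorParams:
    """Saturable-effect parameters of a uric acid production inhibitor.

    ``r_max`` is the maximum fractional decrease of the production rate
    (dimensionless, in [0, 1]); ``p50`` the plasma concentration (ng/mL)
    at half-maximal effect.
    """

    r_max: float
    p50: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_max <= 1:
            raise ValueError(f"r_max must be in [0, 1], got {self.r_max}")
        if not self.p50 > 0:
            raise ValueError(f"p50 must be > 0, got {self.p50}")


@dataclass(frozen=True)
class ReabsorptionInhibitorParams:
    """Saturable-effect parameters of a uric acid reabsorption inhibitor.

    ``f_max`` is the maximum additive increase of the fractional excretion
    coefficient; ``p50`` the plasma concentration (ng/mL) at half-maximal
    effect.
    """

    f_max: float
    p50: float

    def __post_init__(self) -> None:
        if self.f_max < 0:
            raise ValueError(f"f_max must be >= 0, got {self.f_max}")
        if not self.p50 > 0:
            raise ValueError(f"p50 must be > 0, got {self.p50}")


def production_rate_under_drug(kp0, params: ProductionInhibitorParams, conc):
    """Production rate under a production inhibitor at plasma conc. ``conc``.

    Accepts scalar or array concentration (ng/mL); the result is bounded in
    ``[kp0*(1-r_max), kp0]`` and scales linearly in ``kp0``.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("drug concentration must be >= 0")
    out = kp0 * (1.0 - params.r_max * c / (c + params.p50))
    return float(out) if np.isscalar(conc) or c.ndim == 0 else out


def fe_under_drug(fe0, params: ReabsorptionInhibitorParams, conc):
    """Fractional excretion under a reabsorption inhibitor.

    The effect is additive on top of ``fe0`` and saturates at
    ``fe0 + f_max``.  A result exceeding 1 is nonphysical (more urate in
    urine than filtered) and raises ``ValueError``.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("drug concentration must be >= 0")
    out = fe0 + params.f_max * c / (c + params.p50)
    if np.any(out > 1.0):
        raise ValueError(
            f"fractional excretion exceeds 1 (fe0={fe0}, f_max={params.f_max})"
        )
    return float(out) if np.isscalar(conc) or c.ndim == 0 else out


def max_fractional_excretion(fe0: float, params: ReabsorptionInhibitorParams) -> float:
    """Asymptotic fractional excretion at saturating drug concentration."""
    return fe0 + params.f_max


def oxypurinol_interaction_factor(
    p_pin: float, params: ProductionInhibitorParams, reduction: float = 0.32
) -> float:
    """Serum-urate inflation ratio caused by reduced oxypurinol exposure.

    Lesinurad lowers the daily-average oxypurinol concentration by about
    32%; the production rate is correspondingly less inhibited.  The factor
    returned is the ratio of the production rates (equivalently, of the
    steady-state serum concentrations) at the reduced versus the original
    oxypurinol concentration and is >= 1.
    """
    if not 0 <= reduction < 1:
        raise ValueError(f"reduction must be in [0, 1), got {reduction}")
    if p_pin < 0:
        raise ValueError(f"p_pin must be >= 0, got {p_pin}")
    p_red = (1.0 - reduction) * p_pin
    num = 1.0 - params.r_max * p_red / (p_red + params.p50)
    den = 1.0 - params.r_max * p_pin / (p_pin + params.p50)
    return num / den


def corrected_relative_change(delta_pred: float, factor: float) -> float:
    """Apply an interaction correction factor to a relative change.

    With ``delta = S_on/S_base - 1``, multiplying the on-treatment
    concentration by ``factor`` gives ``factor*(delta + 1) - 1``.
    """
    if delta_pred < -1:
        raise ValueError(f"relative change cannot be below -1, got {delta_pred}")
    return factor * (delta_pred + 1.0) - 1.0


@dataclass(frozen=True)
class ConcentrationProfile:
    """Plasma drug concentration as a function of time.

    ``evaluator`` maps time (h, array) to concentration (ng/mL, >= 0);
    ``support`` is the closed time interval on which the profile is valid
    (evaluation outside it raises); ``checkpoints`` lists times where the
    profile is non-smooth (dose times, observation knots) so integrators
    can place grid points there.
    """

    evaluator: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float] = (-math.inf, math.inf)
    checkpoints: tuple[float, ...] = ()

    def __call__(self, t):
        arr = np.asarray(t, dtype=float)
        lo, hi = self.support
        if np.any(arr < lo - 1e-9) or np.any(arr > hi + 1e-9):
            raise ValueError(
                f"time outside profile support [{lo}, {hi}]"
            )
        out = np.asarray(self.evaluator(np.atleast_1d(arr)), dtype=float)
        if arr.ndim == 0:
            return float(out[0])
        return out.reshape(arr.shape)


def constant_profile(conc: float) -> ConcentrationProfile:
    """Profile with a constant concentration, valid for all times."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return ConcentrationProfile(lambda t: np.full_like(t, float(conc)))


@dataclass(frozen=True)
class StandInPKParams:
    """One-compartment, first-order absorption PK parameters.

    ``ka`` 1/h absorption rate constant, ``cl_f`` apparent clearance L/h,
    ``v_f`` apparent volume L.  Doses in mg; concentrations in ng/mL
    (mg/L x 1000).  When ``ka`` equals the elimination rate the Bateman
    form degenerates and the analytic limit ``ka * t * exp(-ka t)`` is used.
    """

    ka: float
    cl_f: float
    v_f: float

    def __post_init__(self) -> None:
        for name in ("ka", "cl_f", "v_f"):
            if not getattr(self, name) > 0:
                raise ValueError(f"StandInPKParams.{name} must be > 0")

    @property
    def ke(self) -> float:
        return self.cl_f / self.v_f


def standin_pk_profile(
    params: StandInPKParams, regimen: list[tuple[float, float]]
) -> ConcentrationProfile:
    """Concentration profile for a list of ``(dose_mg, time_h)`` doses.

    Superposition of one-compartment first-order-absorption responses; the
    resulting profile is continuous and non-negative, zero at and before
    each dose's administration time (no absorption yet).
    """
    if not regimen:
        raise ValueError("regimen must contain at least one dose")
    doses = np.asarray([d for d, _ in regimen], dtype=float)
    times = np.asarray([t for _, t in regimen], dtype=float)
    if np.any(doses <= 0):
        raise ValueError("dose amounts must be > 0")
    if np.any(np.diff(times) < 0):
        raise ValueError("doses must be sorted by time")
    ka, ke, v_f = params.ka, params.ke, params.v_f

    def evaluator(t: np.ndarray) -> np.ndarray:
        dt = t[:, None] - times[None, :]
        active = dt > 0
        dt = np.where(active, dt, 0.0)
        if abs(ka - ke) > 1e-10 * ka:
            shape = ka / (ka - ke) * (np.exp(-ke * dt) - np.exp(-ka * dt))
        else:  # flip-flop degeneracy: analytic limit
            shape = ka * dt * np.exp(-ka * dt)
        conc_mg_l = (doses[None, :] / v_f) * shape * active
        return 1000.0 * conc_mg_l.sum(axis=1)

    return ConcentrationProfile(evaluator, checkpoints=tuple(times))


def interpolate_observed_concentrations(times, concs) -> ConcentrationProfile:
    """Natural cubic spline through observed concentrations, clipped at 0.

    Requires at least three points with strictly increasing times; the
    support is the observed time range.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 observed concentrations")
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate observation times")
    if np.any(np.diff(t) < 0):
        raise ValueError("observation times must be strictly increasing")
    spline = CubicSpline(t, c, bc_type="natural")
    return ConcentrationProfile(
        lambda x: np.maximum(spline(x), 0.0),
        support=(float(t[0]), float(t[-1])),
        checkpoints=tuple(t),
    )


@dataclass(frozen=True)
class DrugSpec:
    """Configuration entry for one urate-lowering drug.

    ``effect`` is ``"production"`` (xanthine oxidase inhibitor acting on
    kp) or ``"reabsorption"`` (uricosuric acting on fe).  ``max_effect``
    is r_max or f_max respectively.  ``p50_hyper`` is the half-maximal
    concentration estimated separately for hyperuricemic gout subjects
    (None if no separate estimate exists).  ``pk`` parameterizes the
    stand-in one-compartment PK model used to simulate exposure.
    """

    name: str
    effect: str
    max_effect: float
    p50: float
    p50_hyper: float | None
    pk: StandInPKParams

    def __post_init__(self) -> None:
        if self.effect not in ("production", "reabsorption"):
            raise ValueError(f"unknown effect type {self.effect!r}")

    def params(
        self,
        hyperuricemic: bool = False,
        max_effect: float | None = None,
        p50: float | None = None,
    ):
        """Effect parameters, optionally overridden (e.g. by fit estimates)."""
        if p50 is None:
            p50 = (
                self.p50_hyper
                if (hyperuricemic and self.p50_hyper is not None)
                else self.p50
            )
        if max_effect is None:
            max_effect = self.max_effect
        if self.effect == "production":
            return ProductionInhibitorParams(r_max=max_effect, p50=p50)
        return ReabsorptionInhibitorParams(f_max=max_effect, p50=p50)


# Effect parameters estimated from the lesinurad clinical program; PK
# stand-ins chosen so that typical doses reproduce clinically reported
# exposure scales (e.g. daily-average oxypurinol ~10,000 ng/mL on 300 mg
# allopurinol; lesinurad 200 mg Cmax ~9,000 ng/mL).  Oxypurinol "doses"
# are the parent allopurinol doses, with the apparent volume/clearance
# absorbing the metabolic conversion.
DRUG_LIBRARY: dict[str, DrugSpec] = {
    "oxypurinol": DrugSpec(
        name="oxypurinol",
        effect="production",
        max_effect=0.84,
        p50=14000.0,
        p50_hyper=None,
        pk=StandInPKParams(ka=1.0, cl_f=1.25, v_f=41.7),
    ),
    "febuxostat": DrugSpec(
        name="febuxostat",
        effect="production",
        max_effect=1.0,
        p50=87.0,
        p50_hyper=120.0,
        pk=StandInPKParams(ka=1.0, cl_f=7.0, v_f=50.0),
    ),
    "lesinurad": DrugSpec(
        name="lesinurad",
        effect="reabsorption",
        max_effect=0.56,
        p50=11000.0,
        p50_hyper=23000.0,
        pk=StandInPKParams(ka=1.0, cl_f=3.0, v_f=15.0),
    ),
}
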