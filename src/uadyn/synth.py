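"""Seeded generators for virtual subjects, Phase-I-style trials and
Phase-III-style cohorts.

These generators stand in for the proprietary clinical datasets the model
was originally built on: multi-group Phase-I trials (serial serum uric
acid over 24 h, 6-h urine collection intervals, single and repeated daily
dosing of a uricosuric alone or combined with a xanthine oxidase
inhibitor), renal-impairment cohorts spanning a wide GFR range, and
Phase-III-style cohorts of hyperuricemic patients with monthly on-treatment
serum values.

Every subject is constructed to satisfy the steady-state mass balance
exactly at baseline (the production rate is back-calculated from the
sampled baseline concentration), and all randomness flows from explicit
seeds through per-purpose generator streams so that subsets of a design
stay reproducible when other parts change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MG_DL_TO_MG_L, ML_MIN_TO_L_H, PhysiologyState
from .drugs import (
    DRUG_LIBRARY,
    DrugSpec,
    ReabsorptionInhibitorParams,
    standin_pk_profile,
)
from .estimate import DrugExposure, ErrorModel, TreatmentGroup
from .qualify import (
    DEFAULT_OXYPURINOL_REDUCTION,
    Phase3Subject,
)
from .drugs import oxypurinol_interaction_factor
from .simulate import SimulationPlan, run_simulation

__all__ = [
    "PopulationSpec",
    "Regimen",
    "GroupDesign",
    "TrialDesign",
    "sample_population",
    "generate_trial",
    "generate_phase3_cohort",
    "DEFAULT_SERUM_ERROR",
    "DEFAULT_URINE_ERROR",
]

# Residual-error defaults (internal units: serum mg/L, urine mg).  The
# additive serum SD corresponds to 0.45 mg/dL on the clinical scale.
DEFAULT_SERUM_ERROR = ErrorModel(a=4.5, b=0.15)
DEFAULT_URINE_ERROR = ErrorModel(a=50.0, b=0.29)


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional assumptions for a virtual population.

    GFR is uniform over ``gfr_range_ml_min``; the baseline fractional
    excretion is log-normal (median/geometric SD), reflecting the 7-12%
    range in healthy adults and renal underexcretion in gout; baseline
    serum uric acid is normal in mg/dL, optionally truncated from below
    (hyperuricemic cohorts: above the 6.8 mg/dL solubility limit).
    """

    n: int = 100
    gfr_range_ml_min: tuple[float, float] = (80.0, 120.0)
    fe0_median: float = 0.07
    fe0_gsd: float = 1.4
    sua_mean_mg_dl: float = 5.5
    sua_sd_mg_dl: float = 0.8
    sua_lower_mg_dl: float | None = None
    hyperuricemic: bool = False
    v_ua: float = 19.0
    cl_i: float = 0.27

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.gfr_range_ml_min
        if not 0 < lo <= hi:
            raise ValueError("gfr_range_ml_min must be positive and ordered")
        if not 0 < self.fe0_median < 1:
            raise ValueError("fe0_median must be in (0, 1)")
        if self.fe0_gsd < 1:
            raise ValueError("fe0_gsd must be >= 1")

    @classmethod
    def hyperuricemic_cohort(cls, n: int) -> "PopulationSpec":
        """Gout-like cohort: renal underexcretion, serum above solubility."""
        return cls(
            n=n,
            gfr_range_ml_min=(30.0, 120.0),
            fe0_median=0.04,
            fe0_gsd=1.4,
            sua_mean_mg_dl=9.0,
            sua_sd_mg_dl=1.5,
            sua_lower_mg_dl=6.8,
            hyperuricemic=True,
        )


def sample_population(spec: PopulationSpec, seed: int) -> list[PhysiologyState]:
    """Draw ``spec.n`` subjects; deterministic for a given seed.

    Draws violating the physiological invariants (fe0 outside (0, 1),
    non-positive serum level) are resampled.  Each subject's production
    rate is back-calculated from their baseline concentration so the
    baseline steady state holds exactly.
    """
    rng = np.random.default_rng(seed)
    sigma = math.log(spec.fe0_gsd)
    out: list[PhysiologyState] = []
    for _ in range(spec.n):
        for _attempt in range(1000):
            gfr_ml_min = rng.uniform(*spec.gfr_range_ml_min)
            fe0 = spec.fe0_median * math.exp(rng.normal(0.0, sigma))
            sua = rng.normal(spec.sua_mean_mg_dl, spec.sua_sd_mg_dl)
            if not 0 < fe0 < 1:
                continue
            if sua <= 0:
                continue
            if spec.sua_lower_mg_dl is not None and sua <= spec.sua_lower_mg_dl:
                continue
            out.append(
                PhysiologyState.from_clinical(
                    gfr_ml_min=gfr_ml_min,
                    fe0=fe0,
                    sua_mg_dl=sua,
                    v_ua=spec.v_ua,
                    cl_i=spec.cl_i,
                )
            )
            break
        else:
            raise ValueError("population spec infeasible: resampling failed")
    return out


@dataclass(frozen=True)
class Regimen:
    """Repeated dosing of one drug: amount (mg) at each listed time (h)."""

    drug: str
    dose_mg: float
    times: tuple[float, ...] = (0.0,)

    def doses(self) -> list[tuple[float, float]]:
        return [(self.dose_mg, t) for t in self.times]


@dataclass(frozen=True)
class GroupDesign:
    """Sampling schedule and regimens of one treatment group.

    ``n_subjects`` controls how many independently noisy observation sets
    the group contributes; all share the group-typical physiology (the
    model describes mean dynamics per arm) but carry independent residual
    noise, emulating the individual samples of a real Phase I arm.
    """

    group_id: str
    regimens: tuple[Regimen, ...]
    serum_times: tuple[float, ...]
    urine_intervals: tuple[tuple[float, float], ...]
    horizon: float
    n_subjects: int = 15
    hyperuricemic: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class TrialDesign:
    """A multi-group Phase-I-style trial with shared error models."""

    groups: tuple[GroupDesign, ...]
    serum_error: ErrorModel = DEFAULT_SERUM_ERROR
    urine_error: ErrorModel = DEFAULT_URINE_ERROR

    def __post_init__(self) -> None:
        for g in self.groups:
            if any(t > g.horizon + 1e-9 for t in g.serum_times):
                raise ValueError(f"group {g.group_id}: serum time beyond horizon")


def _exposures_for(design: GroupDesign, library: dict[str, DrugSpec]):
    exposures = []
    for reg in design.regimens:
        drug = library[reg.drug]
        profile = standin_pk_profile(drug.pk, reg.doses())
        exposures.append(DrugExposure(name=drug.name, effect=drug.effect, profile=profile))
    return exposures


def _plan_for(
    phys: PhysiologyState,
    design: GroupDesign,
    exposures,
    library: dict[str, DrugSpec],
) -> SimulationPlan:
    pin = rin = None
    for exp in exposures:
        drug = library[exp.name]
        params = drug.params(hyperuricemic=design.hyperuricemic)
        if drug.effect == "production":
            if pin is not None:
                raise ValueError("at most one production inhibitor per group")
            pin = (exp.profile, params)
        else:
            if rin is not None:
                raise ValueError("at most one reabsorption inhibitor per group")
            rin = (exp.profile, params)
    return SimulationPlan(
        phys=phys,
        pin=pin,
        rin=rin,
        serum_times=tuple(design.serum_times),
        urine_intervals=tuple(design.urine_intervals),
        horizon=design.horizon,
        dt=0.1,
    )


def _noisy(f: np.ndarray, error: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    y = f + error.sd(f) * rng.standard_normal(f.shape)
    return np.maximum(y, 0.0)


def generate_trial(
    population: list[PhysiologyState],
    design: TrialDesign,
    library: dict[str, DrugSpec] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[TreatmentGroup]]:
    """Simulate group-mean trial data with combined-error residual noise.

    One subject of ``population`` provides the group-typical physiology of
    each design group (the trial models mean dynamics per treatment arm);
    each of the group's ``n_subjects`` virtual subjects contributes an
    independently noisy copy of the observation schedule.  Returns a tidy
    long-format dataset and the ready-to-fit
    :class:`~uadyn.estimate.TreatmentGroup` objects, which share the same
    noisy observations and carry the exact drug exposures used to generate
    them.

    Negative noisy values are truncated at zero.  Separate generator
    streams are used for serum and urine noise so that adding one stream's
    observations does not shift the other's draws.
    """
    if library is None:
        library = DRUG_LIBRARY
    if len(population) < len(design.groups):
        raise ValueError(
            f"need >= {len(design.groups)} subjects, got {len(population)}"
        )
    serum_seed, urine_seed = np.random.SeedSequence(seed).spawn(2)
    rng_serum = np.random.default_rng(serum_seed)
    rng_urine = np.random.default_rng(urine_seed)

    rows: list[dict] = []
    groups: list[TreatmentGroup] = []
    for phys, gdesign in zip(population, design.groups):
        exposures = _exposures_for(gdesign, library)
        plan = _plan_for(phys, gdesign, exposures, library)
        result = run_simulation(plan)
        n_sub = gdesign.n_subjects
        serum_true = result.serum_at(np.asarray(gdesign.serum_times))
        serum_obs = _noisy(
            np.tile(serum_true, (n_sub, 1)), design.serum_error, rng_serum
        )
        urine_obs = _noisy(
            np.tile(result.urine_amounts, (n_sub, 1)), design.urine_error, rng_urine
        )

        for reg in gdesign.regimens:
            for dose, t in reg.doses():
                rows.append(
                    dict(
                        subject_id=gdesign.group_id,
                        group_id=gdesign.group_id,
                        time_h=t,
                        record_type="dose",
                        value=dose,
                        unit="mg",
                        drug=reg.drug,
                        interval_start_h=np.nan,
                        interval_end_h=np.nan,
                    )
                )
        for exp in exposures:
            conc = exp.profile(np.asarray(gdesign.serum_times))
            for t, c in zip(gdesign.serum_times, conc):
                rows.append(
                    dict(
                        subject_id=gdesign.group_id,
                        group_id=gdesign.group_id,
                        time_h=t,
                        record_type="drug_conc",
                        value=c,
                        unit="ng/mL",
                        drug=exp.name,
                        interval_start_h=np.nan,
                        interval_end_h=np.nan,
                    )
                )
        for k in range(n_sub):
            sid = f"{gdesign.group_id}S{k + 1:02d}"
            for t, y in zip(gdesign.serum_times, serum_obs[k]):
                rows.append(
                    dict(
                        subject_id=sid,
                        group_id=gdesign.group_id,
                        time_h=t,
                        record_type="serum_ua",
                        value=y,
                        unit="mg/L",
                        drug="",
                        interval_start_h=np.nan,
                        interval_end_h=np.nan,
                    )
                )
            for (start, end), y in zip(gdesign.urine_intervals, urine_obs[k]):
                rows.append(
                    dict(
                        subject_id=sid,
                        group_id=gdesign.group_id,
                        time_h=end,
                        record_type="urine_ua",
                        value=y,
                        unit="mg",
                        drug="",
                        interval_start_h=start,
                        interval_end_h=end,
                    )
                )
        groups.append(
            TreatmentGroup(
                group_id=gdesign.group_id,
                gfr=phys.gfr,
                fe0=phys.fe0,
                s_ua_base=phys.s_ua_base,
                drugs=tuple(exposures),
                serum_times=np.tile(np.asarray(gdesign.serum_times), n_sub),
                serum_obs=serum_obs.ravel(),
                urine_intervals=tuple(gdesign.urine_intervals) * n_sub,
                urine_obs=urine_obs.ravel(),
                horizon=gdesign.horizon,
                hyperuricemic=gdesign.hyperuricemic,
            )
        )
    return pd.DataFrame(rows), groups


def generate_phase3_cohort(
    population: list[PhysiologyState],
    rin_params: ReabsorptionInhibitorParams,
    *,
    visit_count: int = 6,
    seed: int = 0,
    allopurinol_fraction: float = 0.5,
    serum_error: ErrorModel = DEFAULT_SERUM_ERROR,
    fe_sd: float = 0.01,
    conc_median_ng_ml: float = 8000.0,
    conc_gsd: float = 1.6,
    oxypurinol_conc_ng_ml: float = 10_000.0,
    oxypurinol_reduction: float = DEFAULT_OXYPURINOL_REDUCTION,
) -> list[Phase3Subject]:
    """Phase-III-style cohort of hyperuricemic patients on a uricosuric.

    Each subject receives a steady daily-average drug concentration drawn
    log-normally; the on-treatment fractional excretion follows the
    saturable effect model, and the observed on-treatment serum value is
    the mean of ``visit_count`` noisy monthly steady-state observations.
    A fraction of subjects carries background allopurinol: their achieved
    serum level is inflated by the oxypurinol-exposure interaction factor
    (the same physiology the predictor corrects for).  The measured
    on-treatment fractional excretion carries additive noise ``fe_sd``.

    With all noise set to zero the observed change equals the model
    prediction exactly, by construction.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_conc = np.random.default_rng(ss[0])
    rng_serum = np.random.default_rng(ss[1])
    rng_fe = np.random.default_rng(ss[2])
    rng_allo = np.random.default_rng(ss[3])

    pin = DRUG_LIBRARY["oxypurinol"].params()
    factor = oxypurinol_interaction_factor(
        oxypurinol_conc_ng_ml, pin, oxypurinol_reduction
    )
    subjects: list[Phase3Subject] = []
    for k, phys in enumerate(population):
        conc_drug = conc_median_ng_ml * math.exp(
            rng_conc.normal(0.0, math.log(conc_gsd))
        )
        fe_on = phys.fe0 + rin_params.f_max * conc_drug / (conc_drug + rin_params.p50)
        kp = phys.s_ua_base * (phys.cl_i + phys.gfr * phys.fe0)
        s_on = kp / (phys.cl_i + phys.gfr * fe_on)
        on_allo = bool(rng_allo.random() < allopurinol_fraction)
        if on_allo:
            s_on *= factor
        visits = _noisy(
            np.full(visit_count, s_on), serum_error, rng_serum
        )
        fe_measured = fe_on + (rng_fe.normal(0.0, fe_sd) if fe_sd > 0 else 0.0)
        subjects.append(
            Phase3Subject(
                subject_id=f"P{k + 1:04d}",
                sua_base_mg_dl=phys.s_ua_base / MG_DL_TO_MG_L,
                gfr_ml_min=phys.gfr / ML_MIN_TO_L_H,
                fe0=phys.fe0,
                fe_on=float(fe_measured),
                sua_on_mg_dl=float(visits.mean()) / MG_DL_TO_MG_L,
                on_allopurinol=on_allo,
            )
        )
    return subjects
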