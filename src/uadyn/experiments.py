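"""Parameter-recovery simulation study on synthetic Phase-I-style trials.

This module wires the generators and the estimator into the package's
reference recovery experiment: multi-group trial data are generated at the
published parameter values with combined-error residual noise, refitted
with the maximum-likelihood machinery, and the recovered estimates are
compared with the generating truth across replicates.

The study conditions emulate the structure of the original estimation
dataset at desk scale: twelve treatment groups -- six single-dose
lesinurad monotherapy groups spanning the 50-1600 mg dose range (serial
serum sampling over 24 h and four 6-h urine collection intervals), one
multiple-dose lesinurad group, and once-daily 7-day groups of allopurinol
alone, febuxostat alone, and lesinurad combined with each, sampled on
day 1 and day 7.  The multiple-dose uricosuric arms are what anchors the
intestinal clearance: at the on-drug quasi-steady state the serum level
depends on the ratio of baseline to on-drug total clearance, in which the
intestinal route competes directly with the enhanced renal route.  Two
fits are run per replicate:

* the **main fit** (all six groups) estimates the intestinal clearance,
  the volume of distribution, the oxypurinol and lesinurad half-maximal
  concentrations, and the four residual SDs, with the effect maxima fixed
  at their published values;
* the **monotherapy fit** (lesinurad-alone groups only) re-estimates the
  lesinurad maximal fractional-excretion increase jointly with its
  half-maximal concentration, mirroring how that maximum was originally
  anchored on a wide monotherapy dose range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimate import ErrorModel, FitSpec, FreeParam, fit_ua_model
from .synth import (
    DEFAULT_SERUM_ERROR,
    DEFAULT_URINE_ERROR,
    GroupDesign,
    PopulationSpec,
    Regimen,
    TrialDesign,
    generate_trial,
    sample_population,
)

__all__ = [
    "TRUTH",
    "default_phase1_design",
    "default_population_spec",
    "main_fit_spec",
    "monotherapy_fit_spec",
    "recovery_experiment",
]

# Generating truth: disposition and drug-effect parameters as published,
# residual SDs in internal units (serum mg/L, urine mg).
TRUTH: dict[str, float] = {
    "cl_i": 0.27,
    "v_ua": 19.0,
    "oxypurinol.max_effect": 0.84,
    "oxypurinol.p50": 14000.0,
    "lesinurad.max_effect": 0.56,
    "lesinurad.p50": 11000.0,
    "febuxostat.max_effect": 1.0,
    "febuxostat.p50": 87.0,
    "serum.a": DEFAULT_SERUM_ERROR.a,
    "serum.b": DEFAULT_SERUM_ERROR.b,
    "urine.a": DEFAULT_URINE_ERROR.a,
    "urine.b": DEFAULT_URINE_ERROR.b,
}

_SINGLE_DOSE_SERUM = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0)
_SINGLE_DOSE_URINE = ((0.0, 6.0), (6.0, 12.0), (12.0, 18.0), (18.0, 24.0))
_QD7_DOSE_TIMES = tuple(float(24 * k) for k in range(7))
_QD7_SERUM = (0.0, 2.0, 6.0, 12.0, 24.0, 144.0, 146.0, 150.0, 156.0, 162.0, 168.0)
_QD7_URINE = (
    (0.0, 6.0),
    (6.0, 12.0),
    (12.0, 18.0),
    (18.0, 24.0),
    (144.0, 150.0),
    (150.0, 156.0),
    (156.0, 162.0),
    (162.0, 168.0),
)


def default_phase1_design(
    serum_error: ErrorModel = DEFAULT_SERUM_ERROR,
    urine_error: ErrorModel = DEFAULT_URINE_ERROR,
) -> TrialDesign:
    """Twelve-group Phase-I-style design (see module docstring)."""
    single = [
        GroupDesign(
            group_id=f"LSN{dose}",
            regimens=(Regimen("lesinurad", float(dose), (0.0,)),),
            serum_times=_SINGLE_DOSE_SERUM,
            urine_intervals=_SINGLE_DOSE_URINE,
            horizon=24.0,
        )
        for dose in (50, 100, 200, 400, 600, 1600)
    ]

    def qd7(group_id: str, *regimens: Regimen) -> GroupDesign:
        return GroupDesign(
            group_id=group_id,
            regimens=regimens,
            serum_times=_QD7_SERUM,
            urine_intervals=_QD7_URINE,
            horizon=168.0,
        )

    multi = [
        qd7("LSN400qd", Regimen("lesinurad", 400.0, _QD7_DOSE_TIMES)),
        qd7("ALLO300qd", Regimen("oxypurinol", 300.0, _QD7_DOSE_TIMES)),
        qd7(
            "LSN200+ALLO300",
            Regimen("lesinurad", 200.0, _QD7_DOSE_TIMES),
            Regimen("oxypurinol", 300.0, _QD7_DOSE_TIMES),
        ),
        qd7(
            "LSN400+ALLO300",
            Regimen("lesinurad", 400.0, _QD7_DOSE_TIMES),
            Regimen("oxypurinol", 300.0, _QD7_DOSE_TIMES),
        ),
        qd7("FBX80qd", Regimen("febuxostat", 80.0, _QD7_DOSE_TIMES)),
        qd7(
            "LSN400+FBX80",
            Regimen("lesinurad", 400.0, _QD7_DOSE_TIMES),
            Regimen("febuxostat", 80.0, _QD7_DOSE_TIMES),
        ),
    ]
    return TrialDesign(
        groups=tuple(single) + tuple(multi),
        serum_error=serum_error,
        urine_error=urine_error,
    )


def default_population_spec(n: int) -> PopulationSpec:
    """Healthy-volunteer population for the Phase-I-style groups."""
    return PopulationSpec(
        n=n,
        gfr_range_ml_min=(80.0, 120.0),
        fe0_median=0.07,
        fe0_gsd=1.4,
        sua_mean_mg_dl=5.5,
        sua_sd_mg_dl=0.8,
    )


_ERROR_FREE = {
    "serum.a": FreeParam(init=2.0, lower=1e-2, upper=50.0),
    "serum.b": FreeParam(init=0.2, lower=1e-3, upper=2.0),
    "urine.a": FreeParam(init=30.0, lower=1e-1, upper=1000.0),
    "urine.b": FreeParam(init=0.2, lower=1e-3, upper=2.0),
}


def main_fit_spec() -> FitSpec:
    """Free disposition + half-maximal parameters; effect maxima fixed."""
    return FitSpec(
        free={
            "cl_i": FreeParam(init=0.5, lower=0.01, upper=5.0),
            "v_ua": FreeParam(init=12.0, lower=2.0, upper=100.0),
            "oxypurinol.p50": FreeParam(init=8000.0, lower=100.0, upper=1e6),
            "lesinurad.p50": FreeParam(init=8000.0, lower=100.0, upper=1e6),
            "febuxostat.p50": FreeParam(init=200.0, lower=1.0, upper=1e5),
            **_ERROR_FREE,
        },
        fixed={
            "oxypurinol.max_effect": TRUTH["oxypurinol.max_effect"],
            "lesinurad.max_effect": TRUTH["lesinurad.max_effect"],
            "febuxostat.max_effect": TRUTH["febuxostat.max_effect"],
        },
    )


def monotherapy_fit_spec() -> FitSpec:
    """Joint f_max + p50 fit on the wide-dose-range monotherapy subset."""
    return FitSpec(
        free={
            "cl_i": FreeParam(init=0.5, lower=0.01, upper=5.0),
            "v_ua": FreeParam(init=12.0, lower=2.0, upper=100.0),
            "lesinurad.p50": FreeParam(init=8000.0, lower=100.0, upper=1e6),
            "lesinurad.max_effect": FreeParam(init=0.3, lower=0.02, upper=0.93),
            **_ERROR_FREE,
        },
    )


def _one_replicate(
    rep: int, pop_seed: int, noise_seed: int, fit_seed: int, n_starts: int
) -> list[dict]:
    design = default_phase1_design()
    population = sample_population(default_population_spec(len(design.groups)), pop_seed)
    _, groups = generate_trial(population, design, seed=noise_seed)

    rows: list[dict] = []
    main = fit_ua_model(groups, main_fit_spec(), n_starts=n_starts, seed=fit_seed)
    for name in ("cl_i", "v_ua", "oxypurinol.p50", "lesinurad.p50"):
        rows.append(
            dict(
                replicate=rep,
                fit="main",
                param=name,
                truth=TRUTH[name],
                estimate=main.estimates[name],
                se=main.se[name],
                converged=main.converged,
            )
        )
    mono_groups = [
        g for g in groups if g.group_id.startswith("LSN") and "+" not in g.group_id
    ]
    mono = fit_ua_model(mono_groups, monotherapy_fit_spec(), n_starts=n_starts, seed=fit_seed + 1)
    for name in ("lesinurad.max_effect", "lesinurad.p50"):
        rows.append(
            dict(
                replicate=rep,
                fit="monotherapy",
                param=name,
                truth=TRUTH[name],
                estimate=mono.estimates[name],
                se=mono.se[name],
                converged=mono.converged,
            )
        )
    return rows


def recovery_experiment(
    seed: int, n_replicates: int = 20, n_starts: int = 5
) -> pd.DataFrame:
    """Run the replicate recovery study; one row per (replicate, parameter).

    Columns: replicate, fit ("main"/"monotherapy"), param, truth, estimate,
    se (asymptotic), converged.  All randomness (population draws, residual
    noise, optimizer multistarts) derives from ``seed``.
    """
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rows: list[dict] = []
    for rep, child in enumerate(children):
        pop_seed, noise_seed, fit_seed = (
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in child.spawn(3)
        )
        rows.extend(_one_replicate(rep, pop_seed, noise_seed, fit_seed, n_starts))
    return pd.DataFrame(rows)


def recovery_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter summary: mean estimate and 2-SE coverage of truth."""
    def agg(df: pd.DataFrame) -> pd.Series:
        within = np.abs(df["estimate"] - df["truth"]) <= 2.0 * df["se"]
        return pd.Series(
            {
                "truth": df["truth"].iloc[0],
                "mean_estimate": df["estimate"].mean(),
                "mean_se": df["se"].mean(),
                "coverage_2se": within.mean(),
                "n_replicates": len(df),
            }
        )

    return (
        results.groupby(["fit", "param"])[["estimate", "truth", "se"]]
        .apply(agg)
        .reset_index()
    )
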