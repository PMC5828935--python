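"""Likelihood, fitting machinery and adequacy diagnostics."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from uadyn.core import PhysiologyState
from uadyn.drugs import DRUG_LIBRARY
from uadyn.estimate import (
    DrugExposure,
    ErrorModel,
    FitSpec,
    FreeParam,
    TreatmentGroup,
    adequacy_report,
    fit_ua_model,
    neg_log_likelihood,
    prepare_groups,
    weighted_residuals,
)
from uadyn.estimate import _predict_group
from uadyn.experiments import (
    TRUTH,
    default_phase1_design,
    default_population_spec,
    monotherapy_fit_spec,
)
from uadyn.simulate import SimulationPlan, run_simulation
from uadyn.synth import generate_trial, sample_population

BASE_ERRORS = {
    "serum.a": TRUTH["serum.a"],
    "serum.b": TRUTH["serum.b"],
    "urine.a": TRUTH["urine.a"],
    "urine.b": TRUTH["urine.b"],
}


def _drug_free_group(phys: PhysiologyState, serum_obs, urine_obs) -> TreatmentGroup:
    serum_obs = np.asarray(serum_obs, float)
    urine_obs = np.asarray(urine_obs, float)
    return TreatmentGroup(
        group_id="flat",
        gfr=phys.gfr,
        fe0=phys.fe0,
        s_ua_base=phys.s_ua_base,
        serum_times=np.linspace(0, 24, serum_obs.size),
        serum_obs=serum_obs,
        urine_intervals=tuple(
            (6.0 * k, 6.0 * (k + 1)) for k in range(urine_obs.size)
        ),
        urine_obs=urine_obs,
        horizon=24.0,
    )


class TestNegLogLikelihood:
    def test_matches_direct_density_evaluation(self, healthy_phys):
        # Drug-free group: predictions are flat at the baseline; the NLL must
        # equal the summed Gaussian log-densities evaluated independently.
        f_serum = healthy_phys.s_ua_base
        f_urine = healthy_phys.gfr * healthy_phys.fe0 * f_serum * 6.0
        serum_obs = [55.0, 61.0, 58.5]
        urine_obs = [140.0]
        group = _drug_free_group(healthy_phys, serum_obs, urine_obs)
        params = {"cl_i": healthy_phys.cl_i, "v_ua": healthy_phys.v_ua, **BASE_ERRORS}
        nll = neg_log_likelihood(params, [group])
        sd_s = math.sqrt(TRUTH["serum.a"] ** 2 + (TRUTH["serum.b"] * f_serum) ** 2)
        sd_u = math.sqrt(TRUTH["urine.a"] ** 2 + (TRUTH["urine.b"] * f_urine) ** 2)
        expected = -sum(
            stats.norm.logpdf(y, loc=f_serum, scale=sd_s) for y in serum_obs
        ) - stats.norm.logpdf(urine_obs[0], loc=f_urine, scale=sd_u)
        assert nll == pytest.approx(expected, abs=1e-12)

    def test_additive_limit(self, healthy_phys):
        # b = 0 reduces to the ordinary additive-Gaussian NLL.
        group = _drug_free_group(healthy_phys, [50.0, 70.0], [100.0])
        params = {
            "cl_i": healthy_phys.cl_i,
            "v_ua": healthy_phys.v_ua,
            "serum.a": 2.0,
            "serum.b": 0.0,
            "urine.a": 30.0,
            "urine.b": 0.0,
        }
        f_serum = healthy_phys.s_ua_base
        f_urine = healthy_phys.gfr * healthy_phys.fe0 * f_serum * 6.0
        expected = sum(
            0.5 * math.log(2 * math.pi) + math.log(2.0) + 0.5 * ((y - f_serum) / 2.0) ** 2
            for y in (50.0, 70.0)
        ) + (
            0.5 * math.log(2 * math.pi)
            + math.log(30.0)
            + 0.5 * ((100.0 - f_urine) / 30.0) ** 2
        )
        assert neg_log_likelihood(params, [group]) == pytest.approx(expected, abs=1e-10)

    def test_zero_residual_single_observation(self, healthy_phys):
        f_serum = healthy_phys.s_ua_base
        f_urine = healthy_phys.gfr * healthy_phys.fe0 * f_serum * 6.0
        group = _drug_free_group(healthy_phys, [f_serum], [f_urine])
        params = {"cl_i": healthy_phys.cl_i, "v_ua": healthy_phys.v_ua, **BASE_ERRORS}
        sd_s = math.sqrt(TRUTH["serum.a"] ** 2 + (TRUTH["serum.b"] * f_serum) ** 2)
        sd_u = math.sqrt(TRUTH["urine.a"] ** 2 + (TRUTH["urine.b"] * f_urine) ** 2)
        expected = (0.5 * math.log(2 * math.pi) + math.log(sd_s)) + (
            0.5 * math.log(2 * math.pi) + math.log(sd_u)
        )
        assert neg_log_likelihood(params, [group]) == pytest.approx(expected, abs=1e-12)

    def test_observation_order_invariance(self, healthy_phys):
        params = {"cl_i": healthy_phys.cl_i, "v_ua": healthy_phys.v_ua, **BASE_ERRORS}
        obs = [40.0, 75.0, 66.0, 51.0]
        a = neg_log_likelihood(
            params, [_drug_free_group(healthy_phys, obs, [90.0, 150.0])]
        )
        b = neg_log_likelihood(
            params, [_drug_free_group(healthy_phys, obs[::-1], [150.0, 90.0])]
        )
        assert a == pytest.approx(b, abs=1e-12)


class TestFastPathAgainstReference:
    def test_matches_adaptive_integrator_on_combination_group(self):
        # Dual route: the fixed-grid integrating-factor path used inside the
        # likelihood must agree with the adaptive LSODA reference simulation.
        design = default_phase1_design()
        pop = sample_population(default_population_spec(len(design.groups)), 42)
        _, groups = generate_trial(pop, design, seed=3)
        combo = next(g for g in groups if g.group_id == "LSN400+ALLO300")
        prep = prepare_groups([combo], dt=0.05)[0]
        serum_pred, urine_pred = _predict_group(prep, TRUTH)

        phys = PhysiologyState(
            gfr=combo.gfr,
            fe0=combo.fe0,
            kp0=combo.s_ua_base * (TRUTH["cl_i"] + combo.gfr * combo.fe0),
            v_ua=TRUTH["v_ua"],
            cl_i=TRUTH["cl_i"],
            s_ua_base=combo.s_ua_base,
        )
        exposures = {e.name: e.profile for e in combo.drugs}
        plan = SimulationPlan(
            phys=phys,
            pin=(exposures["oxypurinol"], DRUG_LIBRARY["oxypurinol"].params()),
            rin=(exposures["lesinurad"], DRUG_LIBRARY["lesinurad"].params()),
            serum_times=tuple(np.unique(combo.serum_times)),
            urine_intervals=combo.urine_intervals[: len(set(combo.urine_intervals))],
            horizon=combo.horizon,
        )
        ref = run_simulation(plan)
        ref_serum = ref.serum_at(combo.serum_times)
        n_unique = len(set(combo.urine_intervals))
        assert np.allclose(serum_pred, ref_serum, rtol=2e-3)
        assert np.allclose(urine_pred[:n_unique], ref.urine_amounts, rtol=2e-3)


class TestWeightedResiduals:
    def test_hand_computed_value(self):
        r = weighted_residuals([6.45], [6.0], ErrorModel(a=0.45, b=0.15))
        assert r[0] == pytest.approx(0.45 / 1.0062306, rel=1e-5)

    def test_zero_for_exact_prediction(self):
        assert weighted_residuals([5.0], [5.0], ErrorModel(0.3, 0.1))[0] == 0.0

    def test_standardized_at_scale(self, rng):
        # Residuals of correctly specified data have mean ~0 and SD ~1.
        f = rng.uniform(30, 120, 20_000)
        err = ErrorModel(a=4.5, b=0.15)
        y = f + err.sd(f) * rng.standard_normal(f.size)
        r = weighted_residuals(y, f, err)
        assert abs(r.mean()) < 0.02
        assert r.std() == pytest.approx(1.0, abs=0.02)


def _small_lesinurad_groups(noise_free=True):
    design = default_phase1_design()
    keep = ("LSN200", "LSN600")
    groups_design = tuple(
        dataclasses.replace(g, n_subjects=3) for g in design.groups if g.group_id in keep
    )
    errors = (
        dict(serum_error=ErrorModel(1e-9, 0.0), urine_error=ErrorModel(1e-9, 0.0))
        if noise_free
        else {}
    )
    small = dataclasses.replace(design, groups=groups_design, **errors)
    pop = sample_population(default_population_spec(2), 5)
    _, groups = generate_trial(pop, small, seed=11)
    return groups


class TestFitUaModel:
    def test_zero_noise_recovery(self):
        # Noise-free data generated at known parameters: the optimizer must
        # return the generating values to its own tolerance.
        groups = _small_lesinurad_groups(noise_free=True)
        spec = FitSpec(
            free={
                "cl_i": FreeParam(init=0.4, lower=0.01, upper=5.0),
                "v_ua": FreeParam(init=14.0, lower=2.0, upper=100.0),
                "lesinurad.p50": FreeParam(init=7000.0, lower=100.0, upper=1e6),
            },
            fixed={
                "lesinurad.max_effect": TRUTH["lesinurad.max_effect"],
                "serum.a": 0.1,
                "serum.b": 0.0,
                "urine.a": 1.0,
                "urine.b": 0.0,
            },
        )
        fit = fit_ua_model(groups, spec, n_starts=2, seed=0)
        assert fit.estimates["cl_i"] == pytest.approx(TRUTH["cl_i"], rel=5e-3)
        assert fit.estimates["v_ua"] == pytest.approx(TRUTH["v_ua"], rel=5e-3)
        assert fit.estimates["lesinurad.p50"] == pytest.approx(
            TRUTH["lesinurad.p50"], rel=2e-2
        )
        assert all(n in fit.rse for n in fit.param_names)

    def test_one_dimensional_fit_matches_grid_search(self):
        # Fixing all but cl_i reduces to a 1-D problem whose optimum must
        # match an independent grid search over the same objective.
        groups = _small_lesinurad_groups(noise_free=False)
        fixed = {k: v for k, v in TRUTH.items() if k != "cl_i"}
        spec = FitSpec(
            free={"cl_i": FreeParam(init=0.6, lower=0.02, upper=3.0)}, fixed=fixed
        )
        fit = fit_ua_model(groups, spec, n_starts=1, seed=0)
        grid = np.linspace(0.05, 1.2, 400)
        prepared = prepare_groups(groups, 0.05)
        nlls = [
            neg_log_likelihood({"cl_i": c}, groups, spec, _prepared=prepared)
            for c in grid
        ]
        best_grid = grid[int(np.argmin(nlls))]
        assert fit.estimates["cl_i"] == pytest.approx(best_grid, abs=grid[1] - grid[0])

    def test_profile_likelihood_locally_convex(self):
        groups = _small_lesinurad_groups(noise_free=False)
        spec = monotherapy_fit_spec()
        fit = fit_ua_model(groups, spec, n_starts=2, seed=3)
        prepared = prepare_groups(groups, 0.05)
        base = neg_log_likelihood(fit.estimates, groups, spec, _prepared=prepared)
        for name in fit.param_names:
            for factor in (0.97, 1.03):
                perturbed = dict(fit.estimates)
                perturbed[name] = perturbed[name] * factor
                assert (
                    neg_log_likelihood(perturbed, groups, spec, _prepared=prepared)
                    >= base - 1e-6
                ), name


class TestAdequacy:
    def test_well_specified_fit_passes(self):
        # includes a multiple-dose arm so the intestinal clearance is well
        # identified and its relative SE stays below the adequacy threshold
        design = default_phase1_design()
        keep = ("LSN200", "LSN600", "LSN400qd")
        small = dataclasses.replace(
            design, groups=tuple(g for g in design.groups if g.group_id in keep)
        )
        pop = sample_population(default_population_spec(3), 5)
        _, groups = generate_trial(pop, small, seed=11)
        fixed = {k: v for k, v in TRUTH.items() if k not in ("cl_i", "v_ua")}
        spec = FitSpec(
            free={
                "cl_i": FreeParam(init=0.4, lower=0.02, upper=3.0),
                "v_ua": FreeParam(init=15.0, lower=2.0, upper=100.0),
            },
            fixed=fixed,
        )
        fit = fit_ua_model(groups, spec, n_starts=1, seed=0)
        report = adequacy_report(fit)
        assert not report.rse_flags
        assert not any(report.trend_flags.values())
        assert report.passed

    def test_high_rse_flagged(self):
        groups = _small_lesinurad_groups(noise_free=False)
        fixed = {k: v for k, v in TRUTH.items() if k != "cl_i"}
        spec = FitSpec(
            free={"cl_i": FreeParam(init=0.3, lower=0.02, upper=3.0)}, fixed=fixed
        )
        fit = fit_ua_model(groups, spec, n_starts=1, seed=0)
        fit.rse["cl_i"] = 45.0  # imprecise parameter
        report = adequacy_report(fit)
        assert "cl_i" in report.rse_flags and not report.passed

    def test_misspecified_effect_model_flags_trend(self):
        # Data generated with a saturable excretion effect, fitted with a
        # quasi-linear one (p50 pinned far above the observed exposures):
        # residuals must show a systematic trend.
        design = default_phase1_design()
        keep = ("LSN50", "LSN200", "LSN600", "LSN1600")
        small = dataclasses.replace(
            design, groups=tuple(g for g in design.groups if g.group_id in keep)
        )
        pop = sample_population(default_population_spec(4), 5)
        _, groups = generate_trial(pop, small, seed=11)
        spec = FitSpec(
            free={
                "cl_i": FreeParam(init=0.3, lower=0.02, upper=3.0),
                "v_ua": FreeParam(init=15.0, lower=2.0, upper=100.0),
                "lesinurad.max_effect": FreeParam(init=0.5, lower=0.001, upper=50.0),
                "serum.a": FreeParam(init=2.0, lower=1e-2, upper=50.0),
                "serum.b": FreeParam(init=0.2, lower=1e-3, upper=2.0),
                "urine.a": FreeParam(init=30.0, lower=1e-1, upper=1000.0),
                "urine.b": FreeParam(init=0.2, lower=1e-3, upper=2.0),
            },
            fixed={"lesinurad.p50": 1e6},  # forces a near-linear conc-effect
        )
        fit = fit_ua_model(groups, spec, n_starts=1, seed=0)
        report = adequacy_report(fit)
        assert any(report.trend_flags.values())


def test_group_invariants_enforced(healthy_phys):
    with pytest.raises(ValueError, match="serum"):
        TreatmentGroup(
            group_id="bad",
            gfr=healthy_phys.gfr,
            fe0=healthy_phys.fe0,
            s_ua_base=healthy_phys.s_ua_base,
            serum_times=np.array([]),
            serum_obs=np.array([]),
            urine_intervals=((0.0, 6.0),),
            urine_obs=np.array([100.0]),
        )
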