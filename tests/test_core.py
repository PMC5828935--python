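"""Disposition state equations, steady states and baseline back-calculation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from uadyn.core import (
    PhysiologyState,
    UAState,
    baseline_fractional_excretion,
    baseline_production_rate,
    cockcroft_gault,
    convert_units,
    steady_state,
    ua_derivatives,
)


class TestDerivatives:
    def test_steady_state_balance(self, fig9_phys):
        # At the analytic steady state the serum balance is exactly zero and
        # the urinary appearance rate equals gfr*fe*[S].
        state = UAState(s_ua=120.0 * fig9_phys.v_ua)
        ds, du = ua_derivatives(state, kp=45.36, fe=0.03, phys=fig9_phys)
        assert ds == pytest.approx(0.0, abs=1e-12)
        assert du == pytest.approx(12.96, rel=1e-12)

    def test_empty_system(self, fig9_phys):
        ds, du = ua_derivatives(UAState(s_ua=0.0), kp=0.0, fe=0.05, phys=fig9_phys)
        assert (ds, du) == (0.0, 0.0)

    def test_no_renal_route(self):
        phys = PhysiologyState(gfr=3.6, fe0=0.03, kp0=10.0, v_ua=1.0, cl_i=0.27)
        ds, du = ua_derivatives(UAState(s_ua=50.0), kp=10.0, fe=0.0, phys=phys)
        assert du == 0.0
        assert ds == pytest.approx(10.0 - 13.5)

    def test_rejects_nonfinite_naming_field(self, fig9_phys):
        with pytest.raises(ValueError, match="kp"):
            ua_derivatives(UAState(s_ua=1.0), kp=np.nan, fe=0.1, phys=fig9_phys)
        with pytest.raises(ValueError, match="fe"):
            ua_derivatives(UAState(s_ua=1.0), kp=1.0, fe=np.inf, phys=fig9_phys)

    def test_rejects_out_of_range(self, fig9_phys):
        with pytest.raises(ValueError):
            ua_derivatives(UAState(s_ua=1.0), kp=-1.0, fe=0.1, phys=fig9_phys)
        with pytest.raises(ValueError):
            ua_derivatives(UAState(s_ua=1.0), kp=1.0, fe=1.5, phys=fig9_phys)


class TestSteadyState:
    def test_worked_example(self, fig9_phys):
        ss = steady_state(fig9_phys, kp=45.36, fe=0.03)
        assert ss.conc == pytest.approx(120.0, rel=1e-12)
        assert ss.x_ua == pytest.approx(12.96, rel=1e-12)
        assert ss.cl_total == pytest.approx(0.378, rel=1e-12)

    def test_zero_production(self, fig9_phys):
        ss = steady_state(fig9_phys, kp=0.0)
        assert ss.conc == 0.0 and ss.x_ua == 0.0

    def test_zero_clearance_is_error(self):
        # a degenerate state (all elimination routes closed) has no finite
        # steady state while production continues
        from types import SimpleNamespace

        degenerate = SimpleNamespace(gfr=0.0, fe0=0.0, kp0=10.0, cl_i=0.0)
        with pytest.raises(ValueError, match="steady state"):
            steady_state(degenerate, fe=0.0)

    def test_ode_converges_to_analytic_value(self, fig9_phys):
        # Long-time integration from an arbitrary start must converge to the
        # closed-form steady state to 1e-6 relative.
        phys = fig9_phys
        ss = steady_state(phys)

        def rhs(t, y):
            ds, du = ua_derivatives(UAState(s_ua=y[0], u_ua=y[1]), phys.kp0, phys.fe0, phys)
            return [ds, du]

        for start in (0.0, 5000.0):
            sol = solve_ivp(rhs, (0, 2000.0), [start, 0.0], rtol=1e-10, atol=1e-12)
            conc_end = sol.y[0, -1] / phys.v_ua
            assert conc_end == pytest.approx(ss.conc, rel=1e-6)

    def test_mass_conservation_over_interval(self, fig9_phys):
        # kp*(t1-t0) = dS + integral(cl_i*[S]) + dU over any drug-free window.
        phys = fig9_phys
        y0 = [0.3 * phys.s_ua_base * phys.v_ua, 0.0]  # start far from steady state

        def rhs(t, y):
            ds, du = ua_derivatives(UAState(s_ua=y[0], u_ua=y[1]), phys.kp0, phys.fe0, phys)
            return [ds, du]

        t_grid = np.linspace(0.0, 48.0, 2001)
        sol = solve_ivp(rhs, (0, 48.0), y0, t_eval=t_grid, rtol=1e-10, atol=1e-12)
        conc = sol.y[0] / phys.v_ua
        intestinal = np.trapezoid(phys.cl_i * conc, t_grid)
        lhs = phys.kp0 * 48.0
        rhs_total = (sol.y[0, -1] - y0[0]) + intestinal + sol.y[1, -1]
        assert rhs_total == pytest.approx(lhs, rel=1e-7)

    def test_conc_monotone_decreasing_in_clearance_terms(self):
        # On a grid: steady-state conc strictly decreases in gfr, fe and cl_i
        # and is linear in kp.
        base = dict(gfr=3.6, fe0=0.05, kp0=40.0, cl_i=0.27)
        for name, values in (
            ("gfr", np.linspace(1.0, 10.0, 7)),
            ("fe0", np.linspace(0.01, 0.3, 7)),
            ("cl_i", np.linspace(0.1, 1.0, 7)),
        ):
            concs = [
                steady_state(PhysiologyState(**{**base, name: v})).conc for v in values
            ]
            assert np.all(np.diff(concs) < 0), name
        phys = PhysiologyState(**base)
        for c in (0.5, 2.0, 7.0):
            assert steady_state(phys, kp=c * phys.kp0).conc == pytest.approx(
                c * steady_state(phys).conc, rel=1e-12
            )

    def test_production_scaling_invariance_across_physiologies(self):
        # Scaling kp by c scales conc by exactly c for ANY physiology: the
        # percent serum reduction by a production inhibitor is independent of
        # GFR, fractional excretion and baseline production.
        rng = np.random.default_rng(7)
        for _ in range(20):
            phys = PhysiologyState(
                gfr=rng.uniform(1, 10),
                fe0=rng.uniform(0.01, 0.3),
                kp0=rng.uniform(10, 80),
                v_ua=rng.uniform(10, 30),
                cl_i=rng.uniform(0.1, 0.5),
            )
            c = rng.uniform(0.1, 0.9)
            assert steady_state(phys, kp=c * phys.kp0).conc / steady_state(
                phys
            ).conc == pytest.approx(c, rel=1e-12)


class TestBaselineBackCalculation:
    def test_production_rate_example(self):
        assert baseline_production_rate(120.0, 12.96, 0.27) == pytest.approx(45.36)
        assert baseline_production_rate(50.0, 0.0, 0.0) == 0.0

    def test_fractional_excretion_example(self):
        assert baseline_fractional_excretion(120.0, 12.96, 3.6) == pytest.approx(0.03)
        assert baseline_fractional_excretion(120.0, 0.0, 3.6) == 0.0

    def test_exact_mutual_inverse_with_steady_state(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            phys = PhysiologyState(
                gfr=rng.uniform(1, 10),
                fe0=rng.uniform(0.01, 0.5),
                kp0=rng.uniform(5, 100),
                cl_i=rng.uniform(0.05, 0.6),
            )
            ss = steady_state(phys)
            assert baseline_production_rate(ss.conc, ss.x_ua, phys.cl_i) == pytest.approx(
                phys.kp0, rel=1e-12
            )
            assert baseline_fractional_excretion(
                ss.conc, ss.x_ua, phys.gfr
            ) == pytest.approx(phys.fe0, rel=1e-12)

    def test_fe_above_one_warns(self):
        with pytest.warns(UserWarning, match="> 1"):
            fe = baseline_fractional_excretion(10.0, 100.0, 1.0)
        assert fe == pytest.approx(10.0)

    def test_division_errors(self):
        with pytest.raises(ValueError):
            baseline_fractional_excretion(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            baseline_fractional_excretion(1.0, 1.0, 0.0)


class TestUnits:
    @pytest.mark.parametrize(
        "value,src,dst,expected",
        [
            (12.0, "mg/dL", "mg/L", 120.0),
            (60.0, "mL/min", "L/h", 3.6),
            (2.0, "mg/h", "mg/24h", 48.0),
            (5.0, "mg/L", "mg/L", 5.0),
        ],
    )
    def test_conversions(self, value, src, dst, expected):
        assert convert_units(value, src, dst) == pytest.approx(expected, rel=1e-12)

    def test_round_trip_identity(self):
        for src, dst in (("mg/dL", "mg/L"), ("mL/min", "L/h"), ("mg/h", "mg/24h")):
            assert convert_units(
                convert_units(3.7, src, dst), dst, src
            ) == pytest.approx(3.7, rel=1e-12)

    def test_unsupported_pair(self):
        with pytest.raises(ValueError, match="unsupported"):
            convert_units(1.0, "mg/dL", "mL/min")


class TestCockcroftGault:
    def test_reference_values(self):
        assert cockcroft_gault(40, 72, 1.0, "male") == pytest.approx(100.0)
        assert cockcroft_gault(40, 72, 1.0, "female") == pytest.approx(85.0)

    def test_vanishing_weight(self):
        assert cockcroft_gault(40, 1e-12, 1.0, "male") == pytest.approx(0.0, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cockcroft_gault(140, 72, 1.0, "male")
        with pytest.raises(ValueError):
            cockcroft_gault(40, 72, 1.0, "other")


class TestPhysiologyState:
    def test_from_clinical_is_at_steady_state(self, fig9_phys):
        assert fig9_phys.kp0 == pytest.approx(45.36, rel=1e-12)
        assert fig9_phys.s_ua_base == pytest.approx(120.0, rel=1e-12)
        ss = steady_state(fig9_phys)
        assert ss.conc == pytest.approx(fig9_phys.s_ua_base, rel=1e-12)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PhysiologyState(gfr=-1.0, fe0=0.05, kp0=10.0)
        with pytest.raises(ValueError):
            PhysiologyState(gfr=1.0, fe0=1.5, kp0=10.0)
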