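"""A–Ci linearisations, Rubisco kinetics, and variable-J conductance."""

import numpy as np
import pytest

from nitrophys.aci import (
    ACiCurve,
    KineticConstants,
    f_prime,
    fit_aci,
    fit_jmax,
    fit_vcmax,
    g_prime,
    mesophyll_conductance,
    michaelis_kc,
    michaelis_ko,
)
from nitrophys.errors import (
    InfeasibleFluorescenceError,
    InsufficientDataError,
    NonphysicalConductanceError,
)
from nitrophys.synthdata import CO2_LEVELS, SimConfig, generate_aci_curves

K = KineticConstants()


class TestKinetics:
    def test_kc_ko_at_25C_have_physiological_magnitudes(self):
        assert michaelis_kc(25.0) == pytest.approx(406.0, rel=0.01)
        assert michaelis_ko(25.0) == pytest.approx(277.0, rel=0.01)

    def test_monotone_increasing_in_temperature(self):
        temps = np.linspace(5.0, 45.0, 30)
        kc = [michaelis_kc(t) for t in temps]
        ko = [michaelis_ko(t) for t in temps]
        assert np.all(np.diff(kc) > 0) and np.all(np.diff(ko) > 0)

    def test_arrhenius_ratio_identity(self):
        """kc(T1)/kc(T2) equals exp(Ea/R * (1/T2_K - 1/T1_K))."""
        for func, ea in ((michaelis_kc, 79.43), (michaelis_ko, 36.38)):
            ratio = func(35.0) / func(25.0)
            expected = np.exp(ea / K.r_gas * (1.0 / 298.15 - 1.0 / 308.15))
            assert ratio == pytest.approx(expected, rel=1e-12)


class TestTransforms:
    def test_zero_exactly_at_gamma_star(self):
        assert f_prime(31.0, 25.0) == 0.0
        assert g_prime(31.0) == 0.0

    def test_f_prime_worked_value(self):
        # (200-31)/(200 + Kc*(1 + 210/Ko)) with Kc~406, Ko~277
        assert f_prime(200.0, 25.0) == pytest.approx(0.1853, rel=0.01)

    def test_f_prime_monotone_and_bounded(self):
        ci = np.linspace(1.0, 5000.0, 500)
        vals = f_prime(ci, 25.0)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals < 1.0)

    def test_g_prime_worked_value_and_limit(self):
        assert g_prime(400.0) == pytest.approx(369.0 / 2125.5, abs=1e-12)
        assert g_prime(1e9) == pytest.approx(1.0 / 4.5, rel=1e-6)


def linear_curve(ci, a, **kw):
    return ACiCurve(plant_id="p", ci=np.asarray(ci, float), a_net=np.asarray(a, float), **kw)


class TestWindowRegressions:
    def test_vcmax_exact_on_linear_data(self):
        ci = np.array([60.0, 100.0, 150.0, 200.0])
        a = 100.0 * f_prime(ci, 25.0) - 1.0
        out = fit_vcmax(linear_curve(ci, a))
        assert out["vcmax"] == pytest.approx(100.0, abs=1e-9)
        assert out["rd_light"] == pytest.approx(1.0, abs=1e-9)
        assert out["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_ci_only_is_insufficient(self):
        curve = linear_curve([100.0, 100.0, 100.0], [5.0, 5.1, 4.9])
        with pytest.raises(InsufficientDataError, match="50"):
            fit_vcmax(curve)

    def test_no_points_in_jmax_window(self):
        curve = linear_curve([60.0, 100.0, 150.0], [2.0, 5.0, 8.0])
        with pytest.raises(InsufficientDataError, match="700"):
            fit_jmax(curve)

    def test_point_at_200_belongs_to_both_windows(self):
        ci = np.array([60.0, 120.0, 200.0, 400.0, 600.0])
        a = np.ones_like(ci)
        vc = fit_vcmax(linear_curve(ci, a))
        jm = fit_jmax(linear_curve(ci, a))
        assert vc["n"] == 3 and jm["n"] == 3

    def test_jmax_through_origin_and_intercept_modes(self):
        ci = np.array([200.0, 300.0, 450.0, 600.0, 700.0])
        a = 120.0 * g_prime(ci)
        out = fit_jmax(linear_curve(ci, a))
        assert out["jmax"] == pytest.approx(120.0, abs=1e-9)
        out_b = fit_jmax(linear_curve(ci, a), intercept=True)
        assert out_b["jmax"] == pytest.approx(120.0, abs=1e-8)
        assert out_b["intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_positive_intercept_warns_negative_respiration(self):
        ci = np.array([60.0, 100.0, 150.0, 200.0])
        a = 100.0 * f_prime(ci, 25.0) + 0.5
        with pytest.warns(UserWarning, match="negative respiration"):
            fit_vcmax(linear_curve(ci, a))

    def test_slopes_match_normal_equations_oracle(self, rng):
        """OLS route agrees with an explicit normal-equations solve."""
        for _ in range(20):
            ci = rng.uniform(55.0, 195.0, size=6)
            a = rng.normal(10.0, 2.0, size=6)
            out = fit_vcmax(linear_curve(ci, a))
            x = f_prime(ci, 25.0)
            design = np.column_stack([np.ones(6), x])
            beta = np.linalg.solve(design.T @ design, design.T @ a)
            assert out["vcmax"] == pytest.approx(beta[1], abs=1e-10)
            assert out["rd_light"] == pytest.approx(-beta[0], abs=1e-10)


class TestMesophyllConductance:
    def test_worked_fixture(self):
        # Cc = 31*208/76; gm = 10/(300 - Cc)
        expected = 10.0 / (300.0 - 31.0 * 208.0 / 76.0)
        assert mesophyll_conductance(10.0, 300.0, 120.0, 1.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_infinite_j_limit(self):
        gm = mesophyll_conductance(10.0, 300.0, 1e12, 1.0)
        assert gm == pytest.approx(10.0 / (300.0 - 31.0), rel=1e-6)

    def test_infeasible_fluorescence(self):
        with pytest.raises(InfeasibleFluorescenceError):
            mesophyll_conductance(10.0, 300.0, 44.0, 1.0)  # J = 4*(A+Rd)

    def test_nonphysical_when_cc_exceeds_ci(self):
        with pytest.raises(NonphysicalConductanceError):
            mesophyll_conductance(10.0, 50.0, 120.0, 1.0)


class TestRoundTrips:
    def test_rubisco_branch_recovery(self, noiseless_cfg):
        """Pure Rubisco-limited simulation refits Vcmax/Rd within 2%."""
        cfg = SimConfig(
            seed=0,
            sigma=noiseless_cfg.sigma,
            light_noise_sd=0.0,
            aci_noise_sd=0.0,
            limitation="rubisco",
            aci_params={
                cell: {"vcmax": 100.0, "jmax": 120.0, "gm": 0.2, "rd": 1.0}
                for cell in noiseless_cfg.cells
            },
        )
        curve = generate_aci_curves(cfg)[0]
        out = fit_vcmax(curve)
        assert out["vcmax"] == pytest.approx(100.0, rel=0.02)
        assert out["rd_light"] == pytest.approx(1.0, rel=0.02)

    def test_electron_transport_branch_recovery(self, noiseless_cfg):
        cfg = SimConfig(
            seed=0,
            sigma=noiseless_cfg.sigma,
            light_noise_sd=0.0,
            aci_noise_sd=0.0,
            limitation="et",
            aci_params={
                cell: {"vcmax": 100.0, "jmax": 120.0, "gm": 0.2, "rd": 1.0}
                for cell in noiseless_cfg.cells
            },
        )
        out = fit_jmax(generate_aci_curves(cfg)[0])
        assert out["jmax"] == pytest.approx(120.0, rel=0.02)

    def test_min_limitation_branch_selection(self):
        """With Vcmax=100/Jmax=120 the response is Rubisco-limited at
        Ci=100 and electron-transport-limited at Ci=600."""
        rub = 100.0 * f_prime(np.array([100.0, 600.0]), 25.0) - 1.0
        et = 120.0 * g_prime(np.array([100.0, 600.0]))
        assert rub[0] < et[0]
        assert et[1] < rub[1]

    def test_rubisco_branch_at_gamma_star_equals_minus_rd(self):
        assert 100.0 * f_prime(31.0, 25.0) - 1.0 == pytest.approx(-1.0, abs=1e-12)

    def test_default_cell_full_fit_recovery(self, noiseless_cfg):
        """Noiseless default-parameter curves recover Vcmax, Jmax, Rd,
        and gm within 2% through the full fit."""
        curve = generate_aci_curves(noiseless_cfg)[0]  # deficient/sensitive
        fit = fit_aci(curve)
        truth = noiseless_cfg.aci_params[("deficient", "sensitive")]
        assert fit.vcmax == pytest.approx(truth["vcmax"], rel=0.02)
        assert fit.jmax == pytest.approx(truth["jmax"], rel=0.02)
        assert fit.rd_light == pytest.approx(truth["rd"], rel=0.02)
        assert fit.gm == pytest.approx(truth["gm"], rel=0.02)

    def test_grid_spans_both_windows(self):
        ci = np.array(CO2_LEVELS)
        assert np.sum((ci >= 50) & (ci <= 200)) >= 2
        assert np.sum((ci >= 200) & (ci <= 700)) >= 2
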