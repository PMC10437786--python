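"""Recursive path models: identification, estimation, chi-square fit."""

import numpy as np
import pandas as pd
import pytest

from nitrophys.errors import (
    CollinearityError,
    CyclicGraphError,
    InvalidInputError,
    InvalidParameterError,
)
from nitrophys.pathmodel import (
    BUILTIN_SPECS,
    PathSpec,
    compare_with_ols_oracle,
    fit_path_model,
    model_df,
    simulate_from_path_model,
    standardized_error_variances,
)

CHAIN = PathSpec(("x", "y", "z"), (("x", "y"), ("y", "z")), name="chain")


class TestSpecValidation:
    def test_undeclared_variable_rejected(self):
        with pytest.raises(InvalidInputError):
            PathSpec(("x", "y"), (("x", "w"),))

    def test_self_loop_rejected(self):
        with pytest.raises(CyclicGraphError):
            PathSpec(("x",), (("x", "x"),))

    def test_cycle_rejected(self):
        with pytest.raises(CyclicGraphError):
            PathSpec(("x", "y", "z"), (("x", "y"), ("y", "z"), ("z", "x")))

    def test_merged_builtin_specs_form_a_cycle(self):
        """The three sub-path models cannot be fused into one graph:
        N_Leaf -> Pg_max -> N_FR -> N_Leaf closes a feedback loop."""
        variables, edges = [], []
        for spec in BUILTIN_SPECS.values():
            for v in spec.variables:
                if v not in variables:
                    variables.append(v)
            edges.extend(spec.edges)
        with pytest.raises(CyclicGraphError):
            PathSpec(tuple(variables), tuple(edges), name="merged")

    def test_exogenous_endogenous_partition(self):
        spec = BUILTIN_SPECS["acn"]
        assert set(spec.exogenous) == {"DW_Root", "N_FR"}
        assert set(spec.endogenous) == {"N_Leaf", "ACN", "Area_Leaf", "DW_Shoot"}

    @pytest.mark.parametrize("name,df", [("acn", 9), ("chl", 3), ("pgmax", 10)])
    def test_model_degrees_of_freedom(self, name, df):
        assert model_df(BUILTIN_SPECS[name]) == df


class TestFitting:
    def test_saturated_model_reproduces_sample_covariance(self, rng):
        spec = PathSpec(
            ("a", "b", "c"),
            (("a", "b"), ("a", "c"), ("b", "c")),
            name="saturated",
        )
        data = pd.DataFrame(
            rng.multivariate_normal(
                [0, 0, 0], [[1, 0.4, 0.2], [0.4, 1, 0.5], [0.2, 0.5, 1]], size=80
            ),
            columns=["a", "b", "c"],
        )
        fit = fit_path_model(data, spec)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            fit.implied_cov.to_numpy(), fit.sample_cov.to_numpy(), atol=1e-10
        )

    def test_single_edge_slope_is_pearson_correlation(self, rng):
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        data = pd.DataFrame({"x": x, "y": y})
        spec = PathSpec(("x", "y"), (("x", "y"),))
        fit = fit_path_model(data, spec)
        assert fit.slope("x", "y") == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    def test_ols_oracle_agreement_on_random_dag(self, rng):
        spec = PathSpec(
            ("v1", "v2", "v3", "v4", "v5"),
            (("v1", "v3"), ("v2", "v3"), ("v3", "v4"), ("v1", "v4"), ("v4", "v5")),
        )
        data = pd.DataFrame(
            rng.standard_normal((50, 5)), columns=["v1", "v2", "v3", "v4", "v5"]
        )
        assert compare_with_ols_oracle(data, spec) < 1e-10

    def test_row_permutation_invariance(self, rng):
        data = pd.DataFrame(
            rng.standard_normal((40, 3)), columns=["x", "y", "z"]
        )
        fit = fit_path_model(data, CHAIN)
        shuffled = data.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit_sh = fit_path_model(shuffled, CHAIN)
        pd.testing.assert_frame_equal(fit.edges, fit_sh.edges)
        assert fit.chi2 == pytest.approx(fit_sh.chi2, rel=1e-10)

    def test_chi2_invariant_to_affine_rescaling(self, rng):
        data = pd.DataFrame(
            rng.standard_normal((100, 3)), columns=["x", "y", "z"]
        )
        fit = fit_path_model(data, CHAIN)
        rescaled = data.assign(x=3.0 * data["x"] - 7.0, z=0.1 * data["z"] + 2.0)
        fit_rs = fit_path_model(rescaled, CHAIN)
        assert fit_rs.chi2 == pytest.approx(fit.chi2, rel=1e-9)

    def test_error_variances_are_one_minus_r2(self, rng):
        x = rng.standard_normal(200)
        y = 0.8 * x + 0.6 * rng.standard_normal(200)
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_path_model(data, PathSpec(("x", "y"), (("x", "y"),)))
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert fit.error_variances["y"] == pytest.approx(1.0 - r2, abs=1e-10)
        assert 0.0 <= fit.error_variances["y"] <= 1.0

    def test_missing_rows_dropped_with_count(self, rng):
        data = pd.DataFrame(
            rng.standard_normal((30, 3)), columns=["x", "y", "z"]
        )
        data.loc[3, "y"] = np.nan
        data.loc[11, "z"] = np.nan
        fit = fit_path_model(data, CHAIN)
        assert fit.dropped_rows == 2
        assert fit.n == 28

    def test_collinear_data_rejected_with_variable_names(self, rng):
        x = rng.standard_normal(50)
        data = pd.DataFrame({"x": x, "y": 2.0 * x, "z": rng.standard_normal(50)})
        with pytest.raises(CollinearityError, match="'x' ~ 'y'|'y' ~ 'x'"):
            fit_path_model(data, CHAIN)

    def test_too_few_rows_rejected(self, rng):
        data = pd.DataFrame(rng.standard_normal((3, 3)), columns=["x", "y", "z"])
        with pytest.raises(InvalidInputError, match="n >"):
            fit_path_model(data, CHAIN)


class TestSimulation:
    def test_determinism_under_seed(self):
        slopes = {e: 0.6 for e in CHAIN.edges}
        evars = standardized_error_variances(CHAIN, slopes)
        a = simulate_from_path_model(CHAIN, slopes, evars, n=50, seed=5)
        b = simulate_from_path_model(CHAIN, slopes, evars, n=50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_slopes_give_independent_variables(self):
        slopes = {e: 0.0 for e in CHAIN.edges}
        data = simulate_from_path_model(
            CHAIN, slopes, {"y": 1.0, "z": 1.0}, n=20000, seed=2
        )
        corr = data.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert np.max(np.abs(corr)) < 0.03

    def test_variance_algebra_single_edge(self):
        spec = PathSpec(("x", "y"), (("x", "y"),))
        data = simulate_from_path_model(
            spec, {("x", "y"): 0.8}, {"y": 0.36}, n=100000, seed=3
        )
        assert data["y"].var(ddof=1) == pytest.approx(1.0, abs=0.02)
        assert data["x"].corr(data["y"]) == pytest.approx(0.8, abs=0.01)

    def test_nonpositive_error_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_from_path_model(
                CHAIN, {e: 0.6 for e in CHAIN.edges}, {"y": 0.0, "z": 0.5}, n=10
            )

    def test_unit_variance_error_budget(self):
        slopes = {e: 0.6 for e in BUILTIN_SPECS["acn"].edges}
        evars = standardized_error_variances(BUILTIN_SPECS["acn"], slopes)
        # N_Leaf has two independent parents: e = 1 - 2*0.36
        assert evars["N_Leaf"] == pytest.approx(0.28, abs=1e-12)
        assert evars["ACN"] == pytest.approx(0.64, abs=1e-12)

    def test_oversized_slope_rejected(self):
        with pytest.raises(InvalidParameterError):
            standardized_error_variances(CHAIN, {e: 1.1 for e in CHAIN.edges})

    def test_recovery_bias_vanishes_at_large_n(self):
        slopes = {e: 0.6 for e in CHAIN.edges}
        evars = standardized_error_variances(CHAIN, slopes)
        data = simulate_from_path_model(CHAIN, slopes, evars, n=10000, seed=17)
        fit = fit_path_model(data, CHAIN)
        for s, t in CHAIN.edges:
            assert fit.slope(s, t) == pytest.approx(0.6, abs=0.02)
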