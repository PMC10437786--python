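"""Split-plot ANOVA: oracle agreement, calibration, letters."""

import numpy as np
import pandas as pd
import pytest

from nitrophys.errors import DesignError
from nitrophys.splitplot import (
    MAIN_PLOT,
    REPLICATE,
    SUB_PLOT,
    anova_split_plot,
    check_balance,
    null_rejection_rates,
    tukey_letters,
)


def balanced_table(r=5, rng=None, effects=None):
    """Balanced 2x2xr table of Gaussian noise plus optional cell effects."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for n_level in ("deficient", "optimal"):
        for rep in range(1, r + 1):
            for cult in ("sensitive", "tolerant"):
                mu = (effects or {}).get((n_level, cult), 0.0)
                rows.append(
                    {
                        REPLICATE: rep,
                        MAIN_PLOT: n_level,
                        SUB_PLOT: cult,
                        "y": mu + rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestBalance:
    def test_duplicate_cell_rejected(self):
        df = balanced_table(r=2)
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(DesignError, match="duplicate"):
            check_balance(df)

    def test_missing_cell_rejected(self):
        df = balanced_table(r=2).iloc[:-1]
        with pytest.raises(DesignError, match="unbalanced"):
            check_balance(df)

    def test_missing_design_column_rejected(self):
        df = balanced_table(r=2).drop(columns=[SUB_PLOT])
        with pytest.raises(DesignError):
            check_balance(df)

    def test_single_replicate_rejected(self):
        with pytest.raises(DesignError, match="replicates"):
            anova_split_plot(balanced_table(r=1), "y")


class TestDecomposition:
    def test_ls_means_equal_cell_means(self, rng):
        df = balanced_table(r=5, rng=rng)
        res = anova_split_plot(df, "y")
        for (n_level, cult), mean in res.cell_means.items():
            arithmetic = df[
                (df[MAIN_PLOT] == n_level) & (df[SUB_PLOT] == cult)
            ]["y"].mean()
            assert mean == pytest.approx(arithmetic, abs=1e-12)

    def test_df_partition_sums_to_n_minus_1(self, rng):
        df = balanced_table(r=4, rng=rng)
        res = anova_split_plot(df, "y")
        assert res.anova_table["df"].sum() == len(df) - 1

    @pytest.mark.parametrize("r", [2, 3, 5])
    def test_f_statistics_match_statsmodels_oracle(self, r, rng):
        """Independent route: OLS sequential ANOVA via statsmodels, with
        the main-plot F re-formed against the replicate x N stratum."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = balanced_table(r=r, rng=rng)
        res = anova_split_plot(df, "y")
        model = smf.ols(
            "y ~ C(replicate) + C(n_level) + C(replicate):C(n_level) "
            "+ C(cultivar) + C(n_level):C(cultivar)",
            df,
        ).fit()
        tab = anova_lm(model, typ=1)
        ms = tab["sum_sq"] / tab["df"]
        f_main = ms["C(n_level)"] / ms["C(replicate):C(n_level)"]
        f_sub = ms["C(cultivar)"] / ms["Residual"]
        f_int = ms["C(n_level):C(cultivar)"] / ms["Residual"]
        assert res.f_main == pytest.approx(f_main, rel=1e-10)
        assert res.anova_table.loc["sub", "F"] == pytest.approx(f_sub, rel=1e-10)
        assert res.anova_table.loc["interaction", "F"] == pytest.approx(
            f_int, rel=1e-10
        )

    def test_strong_main_effect_detected_cultivar_null(self):
        rng = np.random.default_rng(7)
        effects = {
            ("optimal", "sensitive"): 10.0,
            ("optimal", "tolerant"): 10.0,
        }
        df = balanced_table(r=5, rng=rng, effects=effects)
        res = anova_split_plot(df, "y")
        assert res.p_main < 1e-3
        assert res.p_sub > 0.01  # no cultivar effect simulated

    def test_zero_residual_flags_degenerate(self):
        df = balanced_table(r=3)
        df["y"] = 1.0 * (df[MAIN_PLOT] == "optimal")
        res = anova_split_plot(df, "y")
        assert res.degenerate

    def test_null_calibration_quick(self):
        rates = null_rejection_rates(n_sims=2000, seed=11)
        for source, rate in rates.items():
            assert abs(rate - 0.05) < 0.02, source


class TestTukeyLetters:
    def test_full_separation_gets_four_letters(self):
        rng = np.random.default_rng(3)
        effects = {
            ("deficient", "sensitive"): 0.0,
            ("deficient", "tolerant"): 100.0,
            ("optimal", "sensitive"): 200.0,
            ("optimal", "tolerant"): 300.0,
        }
        df = balanced_table(r=5, rng=rng, effects=effects)
        res = anova_split_plot(df, "y")
        assert sorted(res.letters.values()) == ["a", "b", "c", "d"]
        # largest mean carries 'a'
        top = max(res.cell_means, key=res.cell_means.get)
        assert res.letters[top] == "a"

    def test_identical_means_share_one_letter(self, rng):
        df = balanced_table(r=5, rng=rng)
        res = anova_split_plot(df, "y")
        assert set(res.letters.values()) == {"a"}

    def test_letters_invariant_to_cell_relabeling(self, rng):
        effects = {
            ("deficient", "sensitive"): 0.0,
            ("deficient", "tolerant"): 8.0,
            ("optimal", "sensitive"): 16.0,
            ("optimal", "tolerant"): 16.5,
        }
        df = balanced_table(r=5, rng=rng, effects=effects)
        res = anova_split_plot(df, "y")
        # swap the main-plot labels; the letter pattern must follow the means
        swapped = df.copy()
        swapped[MAIN_PLOT] = swapped[MAIN_PLOT].map(
            {"deficient": "optimal", "optimal": "deficient"}
        )
        res_sw = anova_split_plot(swapped, "y")
        for (n_level, cult), letters in res.letters.items():
            other = "optimal" if n_level == "deficient" else "deficient"
            assert res_sw.letters[(other, cult)] == letters

    def test_alpha_propagates(self, rng):
        effects = {("deficient", "tolerant"): 2.0}
        df = balanced_table(r=5, rng=rng, effects=effects)
        strict = tukey_letters(anova_split_plot(df, "y"), alpha=1e-6)
        assert set(strict.values()) == {"a"}  # tiny alpha separates nothing
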