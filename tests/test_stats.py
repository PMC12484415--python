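"""ANOVA, post-hoc and stepwise regression against closed forms and
independent library oracles."""

import numpy as np
import pandas as pd
import pytest

from fiberfv.stats import (
    bonferroni_posthoc,
    one_way_f,
    stepwise_regression,
    two_way_anova,
)


def balanced_table(cell_n=5, effects=(0.0, 0.0, 0.0), sd=1.0, seed=0):
    """2x2 design with additive species/type/interaction effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp, sa in (("bonobo", +1), ("human", -1)):
        for ft, sb in (("I", +1), ("II", -1)):
            mu = 10 + effects[0] * sa + effects[1] * sb + effects[2] * sa * sb
            for _ in range(cell_n):
                rows.append({"species": sp, "fiber_type": ft,
                             "y": mu + rng.normal(0, sd)})
    return pd.DataFrame(rows)


def unbalanced_table(seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for sp, sa, ns in (("bonobo", +1, (6, 14)), ("human", -1, (17, 13))):
        for (ft, sb), n in zip((("I", +1), ("II", -1)), ns):
            mu = 5 + 0.8 * sa - 1.1 * sb + 0.5 * sa * sb
            for _ in range(n):
                rows.append({"species": sp, "fiber_type": ft,
                             "y": mu + rng.normal(0, 1.5)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_null_design_f_near_zero(self):
        """All cell means equal: every effect SS is tiny, p large."""
        df = balanced_table(cell_n=50, effects=(0, 0, 0), sd=1.0, seed=1)
        res = two_way_anova(df, "y")
        for eff in res.effects.values():
            assert eff.p > 0.01

    def test_balanced_closed_form_decomposition(self):
        """Balanced 2x2: SS terms equal the textbook cell-mean formulas."""
        df = balanced_table(cell_n=5, effects=(1.3, 0.0, 0.0), seed=2)
        res = two_way_anova(df, "y")
        cells = df.groupby(["species", "fiber_type"])["y"].mean()
        grand = df["y"].mean()
        n = 5
        a_means = df.groupby("species")["y"].mean()
        b_means = df.groupby("fiber_type")["y"].mean()
        ss_a = 2 * n * float(((a_means - grand) ** 2).sum())
        ss_b = 2 * n * float(((b_means - grand) ** 2).sum())
        ss_cells = n * float(((cells - grand) ** 2).sum())
        ss_ab = ss_cells - ss_a - ss_b
        assert res.effects["species"].ss == pytest.approx(ss_a, rel=1e-10)
        assert res.effects["fiber_type"].ss == pytest.approx(ss_b, rel=1e-10)
        assert res.effects["interaction"].ss == pytest.approx(ss_ab, rel=1e-8,
                                                              abs=1e-8)

    def test_type_ii_equals_iii_on_balanced(self):
        df = balanced_table(cell_n=7, effects=(0.9, -0.4, 0.2), seed=3)
        r3 = two_way_anova(df, "y", ss_type=3)
        r2 = two_way_anova(df, "y", ss_type=2)
        for k in r3.effects:
            assert r2.effects[k].ss == pytest.approx(r3.effects[k].ss, rel=1e-9)
            assert r2.effects[k].p == pytest.approx(r3.effects[k].p, rel=1e-9)

    def test_matches_statsmodels_type3_unbalanced(self):
        """Dual-route check against statsmodels anova_lm with sum coding."""
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        df = unbalanced_table(seed=4)
        res = two_way_anova(df, "y", ss_type=3)
        fit = smf.ols(
            "y ~ C(species, Sum) * C(fiber_type, Sum)", data=df
        ).fit()
        tab = anova_lm(fit, typ=3)
        assert res.effects["species"].f == pytest.approx(
            tab.loc["C(species, Sum)", "F"], rel=1e-8)
        assert res.effects["fiber_type"].f == pytest.approx(
            tab.loc["C(fiber_type, Sum)", "F"], rel=1e-8)
        assert res.effects["interaction"].f == pytest.approx(
            tab.loc["C(species, Sum):C(fiber_type, Sum)", "F"], rel=1e-8)
        assert res.effects["species"].p == pytest.approx(
            tab.loc["C(species, Sum)", "PR(>F)"], rel=1e-6)

    def test_one_way_f_equals_t_squared(self):
        from scipy.stats import ttest_ind

        df = unbalanced_table(seed=5)
        res = one_way_f(df, "y", "species")
        a = df.loc[df.species == "bonobo", "y"]
        b = df.loc[df.species == "human", "y"]
        t, p = ttest_ind(a, b, equal_var=True)
        assert res.f == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_empty_cell_type3_errors(self):
        df = balanced_table(cell_n=4, seed=6)
        df = df[~((df.species == "bonobo") & (df.fiber_type == "I"))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(df, "y", ss_type=3)

    def test_dfs_sum_to_n_minus_one(self):
        df = unbalanced_table(seed=7)
        res = two_way_anova(df, "y")
        total_df = sum(e.df for e in res.effects.values()) + res.residual_df
        assert total_df == len(df) - 1


class TestPosthoc:
    def test_single_contrast_unadjusted(self):
        df = unbalanced_table(seed=8)
        cons = bonferroni_posthoc(df, "y",
                                  contrasts=((("bonobo", "I"), ("human", "I")),))
        assert cons[0].p_adjusted == pytest.approx(cons[0].p_raw)

    def test_multiplication_contract(self):
        df = unbalanced_table(seed=9)
        cons = bonferroni_posthoc(df, "y")
        assert len(cons) == 4
        for c in cons:
            assert c.p_adjusted == pytest.approx(min(1.0, 4 * c.p_raw))

    def test_identical_groups_adjusted_p_one(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=12)
        rows = []
        for sp in ("bonobo", "human"):
            for ft in ("I", "II"):
                for v in y:
                    rows.append({"species": sp, "fiber_type": ft, "y": v})
        df = pd.DataFrame(rows)
        cons = bonferroni_posthoc(df, "y")
        for c in cons:
            assert c.p_adjusted == 1.0

    def test_absent_cell_errors(self):
        df = unbalanced_table(seed=11)
        with pytest.raises(ValueError, match="absent"):
            bonferroni_posthoc(df, "y",
                               contrasts=((("bonobo", "I"), ("gorilla", "I")),))


class TestStepwise:
    def make_table(self, n=80, seed=0, signal="vmax", noise=1.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "species": rng.choice(["human", "bonobo"], n),
                "fiber_type": rng.choice(["I", "II"], n),
                "specific_tension": rng.normal(13, 3, n),
                "vmax": rng.normal(0.6, 0.2, n),
                "a_over_po": rng.normal(0.12, 0.04, n),
            }
        )
        if signal is None:
            df["y"] = rng.normal(0, 1, n)
        else:
            df["y"] = 5 * df[signal] + rng.normal(0, noise * 0.05, n)
        return df

    def test_pure_signal_enters_only_signal(self):
        df = self.make_table(signal="vmax")
        res = stepwise_regression(df, "y")
        assert res.entered[0] == "vmax"
        # vmax alone explains essentially everything; entries beyond it are
        # chance-level and must not include a large-coefficient competitor
        assert "vmax" in res.coefficients

    def test_alpha_one_enters_all(self):
        df = self.make_table(signal="vmax", seed=1)
        res = stepwise_regression(df, "y", entry_alpha=1.0)
        assert set(res.entered) == {"species", "fiber_type", "specific_tension",
                                    "vmax", "a_over_po"}

    def test_alpha_zero_enters_none(self):
        df = self.make_table(signal="vmax", seed=2)
        res = stepwise_regression(df, "y", entry_alpha=0.0)
        assert res.entered == []
        assert res.coefficients == {"intercept": pytest.approx(df["y"].mean())}

    def test_entry_p_below_threshold(self):
        df = self.make_table(signal="vmax", seed=3)
        res = stepwise_regression(df, "y")
        for _, p, _ in res.steps:
            assert p < res.entry_alpha

    def test_collinear_candidate_skipped(self):
        df = self.make_table(signal="vmax", seed=4)
        df["vmax_copy"] = df["vmax"]
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_regression(
                df, "y", candidates=("vmax", "vmax_copy"), entry_alpha=1.0
            )
        assert res.entered == ["vmax"]
        assert res.skipped == ("vmax_copy",)

    def test_matches_statsmodels_ols_coefficients(self):
        smapi = pytest.importorskip("statsmodels.api")
        df = self.make_table(signal="vmax", seed=5)
        res = stepwise_regression(df, "y", candidates=("vmax",),
                                  entry_alpha=0.5)
        X = smapi.add_constant(df["vmax"].values)
        fit = smapi.OLS(df["y"].values, X).fit()
        assert res.coefficients["intercept"] == pytest.approx(fit.params[0],
                                                              rel=1e-9)
        assert res.coefficients["vmax"] == pytest.approx(fit.params[1],
                                                         rel=1e-9)
        # adjusted R² trajectory matches the library value
        assert res.steps[0][2] == pytest.approx(fit.rsquared_adj, rel=1e-9)

    def test_too_few_rows_error(self):
        df = self.make_table(n=6, seed=6)
        with pytest.raises(ValueError):
            stepwise_regression(df, "y")
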