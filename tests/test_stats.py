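"""Statistics battery: oracle equivalence, degenerate cases, recovery."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from swimtrack.errors import ValidationError
from swimtrack.stats import (
    check_parametric_assumptions,
    holm_sidak_adjust,
    holm_sidak_posthoc,
    individual_means,
    mixed_model_speed,
    one_way_anova,
    regress_on_regeneration,
)

# fixed three-group fixture used for the sums-of-squares oracle
FIXTURE = pd.DataFrame({
    "treatment": ["a"] * 5 + ["b"] * 4 + ["c"] * 6,
    "y": [6.9, 5.4, 5.8, 4.6, 4.0,
          8.3, 6.8, 7.8, 9.2,
          8.0, 10.5, 8.1, 6.9, 9.3, 9.4],
})


def anova_oracle(groups):
    """Brute-force between/within sums-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


class TestAnova:
    def test_matches_sums_of_squares_oracle_to_six_digits(self):
        res = one_way_anova(FIXTURE, "y")
        groups = [np.asarray(sub["y"]) for _, sub in FIXTURE.groupby("treatment")]
        f_ref, df_b, df_w = anova_oracle(groups)
        assert res.f_stat == pytest.approx(f_ref, rel=1e-7)
        assert (res.df_between, res.df_within) == (df_b, df_w)

    def test_identical_groups_give_f_zero_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        tab = pd.DataFrame({"treatment": np.repeat(["a", "b", "c"], 4),
                            "y": vals * 3})
        res = one_way_anova(tab, "y")
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_variance_everywhere_raises(self):
        tab = pd.DataFrame({"treatment": np.repeat(["a", "b"], 3),
                            "y": [1.0] * 3 + [2.0] * 3})
        with pytest.raises(ValidationError):
            one_way_anova(tab, "y")

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova(FIXTURE[FIXTURE.treatment == "a"], "y")


class TestHolmSidak:
    def test_single_comparison_unchanged(self):
        assert holm_sidak_adjust([0.04]) == pytest.approx([0.04])

    def test_step_down_formula_hand_values(self):
        adj = holm_sidak_adjust([0.01, 0.04, 0.30])
        expected = [1 - 0.99**3, 1 - 0.96**2, 0.30]
        assert adj == pytest.approx(expected, rel=1e-12)

    def test_order_independent_and_monotone(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=6)
            adj = holm_sidak_adjust(p)
            perm = rng.permutation(6)
            assert holm_sidak_adjust(p[perm]) == pytest.approx(adj[perm])
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)
            assert np.all(adj >= p - 1e-12)
            assert np.all((adj >= 0) & (adj <= 1))

    def test_agrees_with_statsmodels(self, rng):
        """Independent cross-check against the reference implementation."""
        for _ in range(25):
            p = rng.uniform(0, 1, size=rng.integers(2, 8))
            ours = holm_sidak_adjust(p)
            _, ref, _, _ = multipletests(p, method="holm-sidak")
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_posthoc_table_shape(self):
        post = holm_sidak_posthoc(FIXTURE, "y")
        assert len(post) == 3  # three pairs
        assert set(post.columns) >= {"pair", "p_raw", "p_adjusted", "significant"}
        assert (post["p_adjusted"] >= post["p_raw"] - 1e-12).all()


class TestRegression:
    @staticmethod
    def _table(x, y):
        return pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(len(x))],
            "treatment": "fifth_gill",
            "regeneration_pct": x,
            "resp": y,
        })

    def test_exact_line_recovered(self):
        x = np.array([10.0, 20.0, 40.0, 55.0, 70.0])
        res = regress_on_regeneration(self._table(x, 2 * x + 1), "resp")
        assert res.slope == pytest.approx(2.0, rel=1e-9)
        assert res.intercept == pytest.approx(1.0, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        x = rng.uniform(30, 85, 9)
        y = 0.01 * x + rng.normal(0, 0.3, 9)
        res = regress_on_regeneration(self._table(x, y), "resp")
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], rel=1e-7)
        assert res.slope == pytest.approx(beta[1], rel=1e-7)

    def test_sham_rows_excluded(self):
        tab = self._table(np.array([30.0, 50.0, 70.0]), np.array([1.0, 2.0, 3.0]))
        sham = pd.DataFrame({
            "individual_id": ["s1", "s2"], "treatment": "sham",
            "regeneration_pct": [np.nan, np.nan], "resp": [99.0, 98.0],
        })
        res = regress_on_regeneration(pd.concat([tab, sham]), "resp")
        assert res.n == 3

    def test_constant_regeneration_undefined(self):
        tab = self._table(np.array([50.0, 50.0, 50.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError):
            regress_on_regeneration(tab, "resp")

    def test_trials_collapsed_to_individual_means(self):
        tab = pd.concat([self._table(np.array([30.0, 50.0, 70.0]),
                                     np.array([1.0, 2.0, 3.0]))] * 4)
        res = regress_on_regeneration(tab, "resp")
        assert res.n == 3  # not 12


def _simulate_design(rng, slope=0.30, b_sd=0.1, resid_sd=0.1,
                     n_ind=11, n_trials=6):
    rows = []
    for i in range(n_ind):
        regen = rng.uniform(33.3, 84.2)
        b = rng.normal(0, b_sd)
        for _ in range(n_trials):
            f = rng.normal(3.9, 0.6)
            rows.append({
                "individual_id": f"i{i}",
                "regeneration_pct": regen,
                "frequency_hz": f,
                "speed_bl_s": 0.2 + slope * f + b + rng.normal(0, resid_sd),
            })
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_recovers_frequency_slope(self, rng):
        mm = mixed_model_speed(_simulate_design(rng))
        fe = mm.fixed_effects.set_index("term")
        assert mm.method == "mixedlm"
        est = fe.loc["frequency_hz"]
        assert est["ci_low"] <= 0.30 <= est["ci_high"]
        assert abs(est["estimate"] - 0.30) < 0.1

    def test_zero_random_variance_matches_ols(self, rng):
        import statsmodels.formula.api as smf

        data = _simulate_design(rng, b_sd=0.0)
        mm = mixed_model_speed(data)
        ols = smf.ols("speed_bl_s ~ frequency_hz * regeneration_pct",
                      data=data).fit()
        assert mm.random_intercept_var < 5e-3
        fe = mm.fixed_effects.set_index("term")
        assert fe.loc["frequency_hz", "estimate"] == pytest.approx(
            ols.params["frequency_hz"], rel=0.01)

    def test_centering_does_not_change_interaction_p(self, rng):
        data = _simulate_design(rng)
        centered = data.copy()
        centered["regeneration_pct"] -= centered["regeneration_pct"].mean()
        p1 = mixed_model_speed(data).fixed_effects.set_index("term").loc[
            "frequency_hz:regeneration_pct", "p"]
        p2 = mixed_model_speed(centered).fixed_effects.set_index("term").loc[
            "frequency_hz:regeneration_pct", "p"]
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_single_trial_per_individual_falls_back_to_ols(self, rng):
        data = _simulate_design(rng, n_trials=1)
        mm = mixed_model_speed(data)
        assert mm.method == "ols_fallback"
        assert mm.warning is not None


class TestAssumptions:
    def test_normal_groups_pass(self, rng):
        tab = pd.DataFrame({"treatment": np.repeat(["a", "b", "c"], 30),
                            "y": rng.normal(0, 1, 90)})
        diag = check_parametric_assumptions(tab, "y")
        assert diag.normality_ok
        assert diag.homoscedastic

    def test_gross_variance_imbalance_fails_levene(self, rng):
        tab = pd.DataFrame({
            "treatment": np.repeat(["a", "b", "c"], 30),
            "y": np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                                 rng.normal(0, 10, 30)]),
        })
        assert not check_parametric_assumptions(tab, "y").homoscedastic

    def test_heavy_tailed_groups_fail_normality_in_majority(self, rng):
        fails = 0
        for _ in range(11):
            tab = pd.DataFrame({"treatment": np.repeat(["a", "b"], 50),
                                "y": rng.lognormal(0, 1, 100)})
            if not check_parametric_assumptions(tab, "y").normality_ok:
                fails += 1
        assert fails > 5

    def test_tiny_group_flagged_underpowered(self):
        tab = pd.DataFrame({"treatment": ["a", "a", "b", "b", "b"],
                            "y": [1.0, 2.0, 1.5, 2.5, 3.0]})
        diag = check_parametric_assumptions(tab, "y")
        assert (diag.shapiro["flag"] == "underpowered").any()


def test_individual_means_keeps_metadata():
    tab = pd.DataFrame({
        "individual_id": ["i1", "i1", "i2"],
        "treatment": ["sham", "sham", "fifth_gill"],
        "regeneration_pct": [np.nan, np.nan, 60.0],
        "y": [1.0, 3.0, 5.0],
    })
    means = individual_means(tab, "y")
    assert len(means) == 2
    assert means.set_index("individual_id").loc["i1", "y"] == 2.0
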