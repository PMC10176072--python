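import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from scfc import (InputError, composite_z, fdr_adjust, fit_linear, fit_lmm,
                  pmm_impute, pool_rubin)
from scfc.stats import build_analysis_table, fit_random_intercept, run_model_table


class TestCompositeZ:
    def test_raws_at_reference_means_give_zero(self):
        ref = {"a": (10.0, 2.0), "b": (5.0, 1.0)}
        assert composite_z({"a": 10.0, "b": 5.0}, ref) == 0.0

    def test_one_sd_above_mean_is_one(self):
        assert composite_z({"a": 12.0}, {"a": (10.0, 2.0)}) == pytest.approx(1.0)

    def test_mean_of_component_zscores(self):
        ref = {"a": (0.0, 1.0), "b": (0.0, 1.0)}
        assert composite_z({"a": 0.4, "b": -0.2}, ref) == pytest.approx(0.1)

    def test_empty_and_bad_sd_rejected(self):
        with pytest.raises(InputError):
            composite_z({}, {})
        with pytest.raises(InputError):
            composite_z({"a": 1.0}, {"a": (0.0, 0.0)})


def linear_table(n=200, beta=1.5, miss_rate=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = 2.0 + beta * x + 0.5 * z + rng.normal(0, 1.0, n)
    df = pd.DataFrame({"x": x, "z": z, "y": y})
    if miss_rate:
        df.loc[rng.random(n) < miss_rate, "y"] = np.nan
    return df


class TestPmmImpute:
    def test_complete_data_returned_unchanged(self):
        df = linear_table()
        out = pmm_impute(df, m=3, rng=0)
        assert len(out) == 3
        for t in out:
            pd.testing.assert_frame_equal(t, df)

    def test_imputed_values_are_observed_donor_values(self):
        df = linear_table(miss_rate=0.15, seed=1)
        observed = set(df["y"].dropna())
        out = pmm_impute(df, m=5, rng=1)
        miss = df["y"].isna()
        for t in out:
            assert not t["y"].isna().any()
            assert set(t.loc[miss, "y"]) <= observed

    def test_imputations_respect_observed_support(self):
        df = linear_table(miss_rate=0.2, seed=2)
        lo, hi = df["y"].min(), df["y"].max()
        for t in pmm_impute(df, m=5, rng=2):
            assert t["y"].between(lo, hi).all()

    def test_pooled_beta_close_to_complete_data_beta(self):
        """MCAR 10%: pooled estimate within 2 pooled-SE of the full-data fit."""
        full = linear_table(n=400, seed=3)
        complete_fit = sm.OLS(full["y"], sm.add_constant(full[["x", "z"]])).fit()
        df = full.copy()
        rng = np.random.default_rng(4)
        df.loc[rng.random(len(df)) < 0.10, "y"] = np.nan
        tables = pmm_impute(df, m=20, rng=5)
        per_imp = []
        for t in tables:
            fit = sm.OLS(t["y"], sm.add_constant(t[["x", "z"]])).fit()
            per_imp.append((fit.params["x"], fit.bse["x"] ** 2))
        pooled = pool_rubin(per_imp, m=20, df_com=complete_fit.df_resid)
        assert abs(pooled.beta - complete_fit.params["x"]) < 2 * pooled.se

    def test_fully_missing_column_rejected(self):
        df = linear_table(n=20)
        df["y"] = np.nan
        with pytest.raises(InputError):
            pmm_impute(df, m=2, rng=0)


class TestFitLinear:
    def test_exact_line_recovered_with_zero_residual(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df["x"]
        fit = fit_linear(df, "y", "x", covariates=())
        beta, var, dof = fit["x"]
        assert beta == pytest.approx(2.0, abs=1e-10)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_null_simulation_type_one_error_near_alpha(self):
        """y independent of x: |t| > 1.96 in about 5% of replicates."""
        rng = np.random.default_rng(6)
        hits = 0
        reps = 400
        for _ in range(reps):
            n = 200
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            df = pd.DataFrame({"x": x, "y": y})
            beta, var, dof = fit_linear(df, "y", "x", covariates=())["x"]
            if abs(beta / np.sqrt(var)) > 1.96:
                hits += 1
        rate = hits / reps
        assert 0.02 <= rate <= 0.09

    def test_recovers_planted_effect_within_2se(self):
        df = linear_table(n=300, beta=1.5, seed=7)
        beta, var, dof = fit_linear(df, "y", "x", covariates=("z",))["x"]
        assert abs(beta - 1.5) < 2 * np.sqrt(var)

    def test_collinear_design_named(self):
        df = linear_table(n=50, seed=8)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(InputError, match="x2|x"):
            fit_linear(df, "y", "x", covariates=("x2",))


def lmm_table(n_subjects=200, sigma_u=1.0, sigma_e=0.5, beta=1.5, seed=0,
              within_exposure=True):
    rng = np.random.default_rng(seed)
    sub = np.repeat(np.arange(n_subjects), 2)
    u = rng.normal(0, sigma_u, n_subjects)[sub]
    if within_exposure:
        x = rng.normal(size=2 * n_subjects)
    else:
        x = rng.normal(size=n_subjects)[sub]  # constant within subject
    df = pd.DataFrame({
        "subject_id": sub,
        "x": x,
        "age": rng.normal(65, 8, 2 * n_subjects),
        "sex": rng.integers(0, 2, 2 * n_subjects).astype(float),
        "global_efficiency": rng.normal(1.0, 0.1, 2 * n_subjects),
        "time_since_baseline": np.tile([0.0, 4.0], n_subjects),
    })
    df["y"] = beta * df["x"] + u + rng.normal(0, sigma_e, 2 * n_subjects)
    return df


class TestFitLmm:
    def test_zero_between_subject_variance_matches_ols(self):
        """When REML puts the random-intercept variance at the zero
        boundary, the mixed model degenerates exactly to OLS."""
        df = lmm_table(sigma_u=0.0, seed=0)
        covs = ("age", "sex", "global_efficiency")
        fit = fit_random_intercept(df, "y", "x", covariates=covs)
        assert fit.theta == 0.0  # boundary reached on this dataset
        ols = fit_linear(df, "y", "x",
                         covariates=(*covs, "time_since_baseline"))
        assert fit.terms["x"][0] == pytest.approx(ols["x"][0], abs=1e-6)
        assert fit.terms["x"][1] == pytest.approx(ols["x"][1], rel=1e-6)

    def test_variance_components_recovered_within_20pct(self):
        fit = fit_random_intercept(lmm_table(sigma_u=1.0, sigma_e=0.5, seed=2),
                                   "y", "x")
        assert fit.sigma_u2 == pytest.approx(1.0, rel=0.2)
        assert fit.sigma_e2 == pytest.approx(0.25, rel=0.2)

    def test_between_subject_exposure_matches_subject_mean_regression(self):
        """Balanced data, exposure constant within subject, no covariates:
        the fixed effect equals OLS on subject means (the between oracle)."""
        df = lmm_table(n_subjects=80, within_exposure=False, seed=3)
        fit = fit_random_intercept(df, "y", "x", covariates=(), time=None)
        means = df.groupby("subject_id")[["x", "y"]].mean()
        oracle = sm.OLS(means["y"], sm.add_constant(means["x"])).fit()
        assert fit.terms["x"][0] == pytest.approx(oracle.params["x"], abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        df = lmm_table(n_subjects=150, seed=4)
        mine = fit_random_intercept(df, "y", "x")
        exog = sm.add_constant(df[["x", "age", "sex", "global_efficiency",
                                   "time_since_baseline"]])
        ref = sm.MixedLM(df["y"], exog, groups=df["subject_id"]).fit(reml=True)
        assert mine.terms["x"][0] == pytest.approx(ref.params["x"], abs=1e-4)
        assert np.sqrt(mine.terms["x"][1]) == pytest.approx(ref.bse["x"], rel=1e-2)
        assert mine.sigma_u2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=5e-2)


class TestPoolRubin:
    def test_worked_example_total_variance_four(self):
        pooled = pool_rubin([(1.0, 1.0), (3.0, 1.0)], m=2)
        assert pooled.beta == 2.0
        assert pooled.within_var == 1.0
        assert pooled.between_var == 2.0
        assert pooled.total_var == 4.0  # W + (1 + 1/2) * 2
        assert pooled.se == 2.0

    def test_identical_estimates_collapse_to_within_variance(self):
        pooled = pool_rubin([(1.2, 0.5)] * 4, m=4)
        assert pooled.between_var == 0.0
        assert pooled.total_var == pooled.within_var

    def test_single_imputation_warns_and_equals_input(self):
        with pytest.warns(UserWarning):
            pooled = pool_rubin([(1.5, 0.4)], m=1)
        assert pooled.beta == 1.5
        assert pooled.total_var == 0.4

    def test_total_never_below_within(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            est = [(rng.normal(), rng.uniform(0.1, 2.0)) for _ in range(5)]
            pooled = pool_rubin(est, m=5)
            assert pooled.total_var >= pooled.within_var


def bh_oracle(p):
    """Hand-rolled Benjamini-Hochberg step-up, independent of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == [pytest.approx(0.03)]

    def test_step_up_worked_example(self):
        adj = fdr_adjust([0.005, 0.01, 0.03, 0.04])
        assert adj == pytest.approx([0.02, 0.02, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_hand_rolled_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=12)
        assert fdr_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        adj = np.asarray(fdr_adjust(p))
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_empty_list(self):
        assert fdr_adjust([]) == []


class TestAnalysisDrivers:
    def test_log_transform_and_time_column(self):
        meta = pd.DataFrame({
            "subject_id": ["a", "a"], "timepoint": [1, 2],
            "age": [60.0, 64.0], "sex": [1, 1], "kappa_true": [0.3, 0.3],
            "cognition": [0.1, 0.2], "processing_speed": [-1.0, -0.9],
            "apathy": [np.e, np.e**2], "depression": [1.0, 1.0]})
        coup = pd.DataFrame({
            "subject_id": ["a", "a"], "timepoint": [1, 2],
            "whole_brain_r": [0.2, 0.21], "global_efficiency": [1.0, 1.0],
            "n_edges_used": [100, 100]})
        table = build_analysis_table(meta, coup, follow_up_years=4.0)
        assert table["log_apathy"].tolist() == pytest.approx([1.0, 2.0])
        assert table["time_since_baseline"].tolist() == [0.0, 4.0]

    def test_nonpositive_raw_apathy_rejected(self):
        meta = pd.DataFrame({
            "subject_id": ["a"], "timepoint": [1], "age": [60.0], "sex": [0],
            "kappa_true": [0.3], "cognition": [0.0], "processing_speed": [0.0],
            "apathy": [-1.0], "depression": [1.0]})
        coup = pd.DataFrame({
            "subject_id": ["a"], "timepoint": [1], "whole_brain_r": [0.2],
            "global_efficiency": [1.0], "n_edges_used": [10]})
        with pytest.raises(InputError):
            build_analysis_table(meta, coup)

    def test_run_model_table_shape_and_fdr_family(self):
        rng = np.random.default_rng(10)
        n = 60
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)] * 2,
            "timepoint": [1] * n + [2] * n,
            "whole_brain_r": np.tile(rng.normal(0.22, 0.05, n), 2),
            "age": np.tile(rng.normal(65, 8, n), 2),
            "sex": np.tile(rng.integers(0, 2, n).astype(float), 2),
            "global_efficiency": np.tile(rng.normal(1, 0.1, n), 2),
        })
        table["time_since_baseline"] = np.where(table.timepoint == 1, 0.0, 4.0)
        table["cognition"] = 1.0 * table.whole_brain_r + rng.normal(0, 0.3, 2 * n)
        table.loc[rng.random(2 * n) < 0.1, "cognition"] = np.nan
        out = run_model_table(table, "cross", ["whole_brain_r"], ["cognition"],
                              m=3, seed=0)
        assert list(out.columns) == ["network", "outcome", "beta", "se", "p",
                                     "p_fdr", "n", "m"]
        assert len(out) == 1
        assert out.p_fdr.iloc[0] >= out.p.iloc[0] - 1e-15
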