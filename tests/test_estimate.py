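"""Fixed-effects 2SLS, cluster-robust covariance, R² statistics, regional tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import smokecast as sc
from smokecast.estimate import _sandwich
from conftest import make_design


def _random_panel(n_states=4, n_years=12, seed=0):
    """Small panel with genuinely stochastic regressors (no collinearity)."""
    rng = np.random.default_rng(seed)
    regions = ["NE", "SE", "FW", "GL", "PL", "SW", "RM", "ME"]
    rows = []
    for i in range(n_states):
        prev, cons, income = 20.0, 400.0, 30000.0
        for t in range(n_years):
            prev *= np.exp(rng.normal(0, 0.05))
            cons *= np.exp(rng.normal(0, 0.05))
            income *= np.exp(rng.normal(0.01, 0.03))
            rows.append({
                "state": f"X{i}", "year": 2000 + t, "region": regions[i % 8],
                "hexp": 4000 * np.exp(rng.normal(0, 0.1)),
                "prev": prev, "cons": cons, "income": income,
                "elderly": 12 * np.exp(rng.normal(0, 0.02)),
                "black": 8 * np.exp(rng.normal(0, 0.02)),
                "hispanic": 6 * np.exp(rng.normal(0, 0.02)),
                "tax": 0.5 * np.exp(rng.normal(0.02, 0.05)),
                "population": 1e6 * (i + 1),
            })
    return sc.StatePanel(pd.DataFrame(rows))


class TestWithinTransform:
    def test_demeaning(self):
        d = make_design([1.0, 2.0, 3.0, 5.0, 7.0], [[1.0], [2.0], [3.0], [5.0], [6.0]],
                        ["a", "a", "a", "b", "b"], [1, 2, 3, 1, 2])
        wd = sc.within_transform(d)
        assert np.allclose(wd.X["x0"].values[:3], [-1.0, 0.0, 1.0])

    def test_idempotence(self, small_panel, default_spec):
        d = sc.build_design(small_panel, default_spec)
        w1 = sc.within_transform(d)
        w2 = sc.within_transform(w1)
        pd.testing.assert_frame_equal(w1.X, w2.X)

    def test_state_constant_column_absorbed_and_reported(self, small_panel):
        spec = sc.ModelSpec(endogenous=(), instruments=())
        d = sc.build_design(small_panel, spec)
        d.X = d.X.copy()
        d.X["flat"] = d.clusters.map({s: float(i) for i, s in enumerate(small_panel.states)})
        wd = sc.within_transform(d)
        assert "flat" in wd.absorbed
        assert "flat" not in wd.X.columns


class TestFit2SLS:
    def test_instruments_equal_to_endogenous_reduce_to_ols(self, small_panel):
        spec_iv = sc.ModelSpec()
        d = sc.build_design(small_panel, spec_iv)
        d.Z = d.X[["cons"]].rename(columns={"cons": "cons_self"})
        iv = sc.fit_2sls(d)
        d_ols = dataclasses.replace(d, endog=[])  # same rows, no instrumenting
        ols = sc.fit_2sls(d_ols)
        pd.testing.assert_series_equal(iv.beta, ols.beta, rtol=1e-10)

    def test_matches_brute_force_two_stage_regressions(self):
        """Just-identified tiny instance vs explicit statsmodels two-stage OLS."""
        panel = _random_panel(n_states=2, n_years=9, seed=5)
        spec = sc.ModelSpec(
            state_vars=("prev", "cons"), cs_averages=(), tax_by_region=False,
            endogenous=("cons",), instruments=(("cons", 2),), lag=1,
        )
        d = sc.build_design(panel, spec)
        fit = sc.fit_2sls(d)

        # oracle: demean by state, run the two regressions explicitly
        def dm(s):
            return (s - s.groupby(d.clusters).transform("mean")).to_numpy()
        y = dm(d.y)
        Xd = np.column_stack([dm(d.X[c]) for c in d.X.columns])
        z = dm(d.Z["cons_lag2"])
        exog_idx = [i for i, c in enumerate(d.X.columns) if c != "cons"]
        j = list(d.X.columns).index("cons")
        W = np.column_stack([Xd[:, exog_idx], z])
        stage1 = sm.OLS(Xd[:, j], W).fit()
        X2 = Xd.copy()
        X2[:, j] = stage1.fittedvalues
        stage2 = sm.OLS(y, X2).fit()
        oracle = {c: stage2.params[i] for i, c in enumerate(d.X.columns)}
        for c in d.X.columns:
            assert fit.beta[c] == pytest.approx(oracle[c], abs=1e-8)

    def test_order_condition_enforced(self, small_panel):
        spec = sc.ModelSpec(endogenous=("cons",), instruments=(("cons", 2),))
        d = sc.build_design(small_panel, spec)
        d.Z = d.Z.iloc[:, :0]
        with pytest.raises(ValueError, match="order condition"):
            sc.fit_2sls(d)

    def test_rank_deficiency_names_columns(self, small_panel):
        spec = sc.ModelSpec(endogenous=(), instruments=())
        d = sc.build_design(small_panel, spec)
        d.X = d.X.copy()
        d.X["dup"] = d.X["prev"] * 2.0
        with pytest.raises(sc.estimate.RankDeficientError, match="dup|prev"):
            sc.fit_2sls(d)

    def test_estimates_invariant_to_state_level_shift(self, small_panel):
        """Adding a constant to one state's response moves only its intercept."""
        spec = sc.ModelSpec(endogenous=(), instruments=())
        d = sc.build_design(small_panel, spec)
        base = sc.fit_2sls(d)
        shifted = dataclasses.replace(d)
        st = small_panel.states[0]
        bump = (d.clusters == st) * 0.7
        shifted.y = d.y + bump
        fit2 = sc.fit_2sls(shifted)
        pd.testing.assert_series_equal(base.beta, fit2.beta, rtol=1e-9)
        assert fit2.fixed_effects[st] - base.fixed_effects[st] == pytest.approx(0.7)

    def test_residuals_sum_to_zero_within_state(self, small_panel, default_spec):
        fit = sc.fit_2sls(sc.build_design(small_panel, default_spec))
        sums = fit.residuals.groupby(level=0).sum()
        assert sums.abs().max() < 1e-9

    def test_vcov_symmetric_psd(self, small_panel, default_spec):
        fit = sc.fit_2sls(sc.build_design(small_panel, default_spec))
        V = fit.vcov.values
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-12


class TestClusterVcov:
    def test_zero_residuals_give_zero_matrix(self, noiseless_panels):
        latent, _, _ = noiseless_panels
        d = sc.build_design(latent, sc.ModelSpec())
        fit = sc.fit_2sls(d)
        assert np.abs(fit.vcov.values).max() < 1e-16

    def test_hand_built_two_cluster_example(self):
        """2 clusters x 2 obs, one regressor: sandwich summed by hand."""
        y = [1.0, 3.0, 2.0, 6.0]
        x = [[1.0], [2.0], [1.0], [3.0]]
        d = make_design(y, x, ["a", "a", "b", "b"], [1, 2, 1, 2])
        fit = sc.fit_2sls(d)
        # demeaned: x_a=(-.5,.5) y_a=(-1,1); x_b=(-1,1) y_b=(-2,2)
        xt = np.array([-0.5, 0.5, -1.0, 1.0])
        yt = np.array([-1.0, 1.0, -2.0, 2.0])
        beta = (xt @ yt) / (xt @ xt)  # = 4.5/2.5 = 1.8
        assert fit.beta["x0"] == pytest.approx(beta)
        u = yt - xt * beta
        meat = (xt[0] * u[0] + xt[1] * u[1]) ** 2 + (xt[2] * u[2] + xt[3] * u[3]) ** 2
        bread = 1.0 / (xt @ xt)
        n, k, g, n_fe = 4, 1, 2, 2
        factor = (g / (g - 1)) * ((n - 1) / (n - k - n_fe))
        assert fit.vcov.values[0, 0] == pytest.approx(bread * meat * bread * factor)

    def test_one_obs_per_cluster_equals_hc_sandwich(self):
        """Singleton clusters: kernel equals HC0 covariance up to the factor."""
        rng = np.random.default_rng(2)
        n, k = 40, 3
        X = rng.standard_normal((n, k))
        beta = np.array([1.0, -0.5, 0.2])
        y = X @ beta + rng.standard_normal(n) * (1 + 0.5 * np.abs(X[:, 0]))
        u = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        ours = _sandwich(X, u, np.arange(n), small_sample=False)
        hc0 = sm.OLS(y, X).fit(cov_type="HC0").cov_params()
        assert np.allclose(ours, hc0, rtol=1e-8)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            _sandwich(np.ones((3, 1)), np.ones(3), np.zeros(3))

    def test_recompute_matches_fit(self, small_panel, default_spec):
        d = sc.build_design(small_panel, default_spec)
        fit = sc.fit_2sls(d)
        V = sc.cluster_robust_vcov(fit, d)
        pd.testing.assert_frame_equal(V, fit.vcov, rtol=1e-10)


class TestConfidenceInterval:
    @pytest.mark.parametrize("est,se,lo,hi", [
        (0.104, 0.0323, 0.0407, 0.167),   # smoking prevalence elasticity
        (0.259, 0.0679, 0.126, 0.392),    # income elasticity
        (0.493, 0.0831, 0.330, 0.656),    # age-structure elasticity
    ])
    def test_reproduces_printed_intervals(self, est, se, lo, hi):
        low, high = sc.confidence_interval(est, se, 0.95)

        def sig3(x):
            return float(f"{x:.3g}")
        assert sig3(low) == lo
        assert sig3(high) == hi

    def test_zero_se_degenerate(self):
        assert sc.confidence_interval(0.3, 0.0, 0.9) == (0.3, 0.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sc.confidence_interval(0.1, -1.0, 0.95)
        with pytest.raises(ValueError):
            sc.confidence_interval(0.1, 1.0, 1.5)


class TestPanelR2:
    def test_perfect_fit_gives_unit_r2(self, noiseless_panels):
        latent, _, _ = noiseless_panels
        d = sc.build_design(latent, sc.ModelSpec())
        fit = sc.fit_2sls(d)
        r2 = sc.panel_r2(fit, d)
        assert r2.within == pytest.approx(1.0, abs=1e-9)
        assert r2.between == pytest.approx(1.0, abs=1e-6)
        assert r2.total == pytest.approx(1.0, abs=1e-9)

    def test_statistics_match_manual_computation(self):
        panel = _random_panel(n_states=3, n_years=10, seed=9)
        spec = sc.ModelSpec(state_vars=("prev", "income"), cs_averages=(),
                            tax_by_region=False, endogenous=(), instruments=())
        d = sc.build_design(panel, spec)
        fit = sc.fit_2sls(d)
        r2 = sc.panel_r2(fit, d)
        xb = pd.Series(d.X.values @ fit.beta.values, index=d.y.index)
        g = d.fe_groups
        within = np.corrcoef(xb - xb.groupby(g).transform("mean"),
                             d.y - d.y.groupby(g).transform("mean"))[0, 1] ** 2
        score_m = xb.groupby(g).mean() + fit.fixed_effects
        between = np.corrcoef(score_m, d.y.groupby(g).mean())[0, 1] ** 2
        assert r2.within == pytest.approx(within)
        assert r2.between == pytest.approx(between)
        sa = fit.fixed_effects.std(ddof=1)
        assert r2.rho == pytest.approx(sa**2 / (sa**2 + fit.sigma**2))
        assert 0 <= r2.rho <= 1
        assert r2.rmse == fit.sigma

    def test_zero_fe_dispersion_gives_zero_rho(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        y = 2 * x + rng.standard_normal(40) * 0.1
        d = make_design(y, x[:, None], ["a"] * 20 + ["b"] * 20,
                        list(range(20)) + list(range(20)))
        # identical intercepts by construction (both groups centered at 0)
        fit = sc.fit_2sls(d)
        r2 = sc.panel_r2(fit, d)
        assert r2.rho < 0.05


class TestFitRegional:
    @staticmethod
    def _design_with_y(panel, beta, region_bump=0.0, noise=0.02, seed=0):
        spec = sc.ModelSpec(endogenous=(), instruments=())
        d = sc.build_design(panel, spec)
        rng = np.random.default_rng(seed)
        b = pd.Series(0.0, index=d.X.columns)
        for k, v in beta.items():
            b[k] = v
        y = d.X.values @ b.values
        y = y + (d.regions == "NE").to_numpy() * region_bump * d.X["prev"].to_numpy()
        alpha = {s: rng.normal(0, 0.1) for s in panel.states}
        y = y + d.clusters.map(alpha).to_numpy() + rng.normal(0, noise, len(y))
        d2 = dataclasses.replace(d)
        d2.y = pd.Series(y, index=d.y.index, name="ln_hexp")
        return d2

    def test_f_matches_textbook_formula_via_statsmodels(self, small_panel):
        d = self._design_with_y(small_panel, {"prev": 0.1, "cons": 0.1}, seed=1)
        het = sc.fit_regional(d, vary=("prev",))
        # oracle: statsmodels with explicit state dummies and interactions
        dummies = pd.get_dummies(d.clusters, drop_first=False).astype(float).values
        Xp = np.column_stack([d.X.values, dummies])
        rss_r = sm.OLS(d.y.values, Xp).fit().ssr
        inter = [d.X["prev"].values * (d.regions == r).values
                 for r in sorted(d.regions.unique())]
        Xu = np.column_stack([d.X.drop(columns="prev").values] + inter + [dummies])
        res_u = sm.OLS(d.y.values, Xu).fit()
        q = len(sorted(d.regions.unique())) - 1
        f_oracle = ((rss_r - res_u.ssr) / q) / (res_u.ssr / res_u.df_resid)
        assert het.f_stat == pytest.approx(f_oracle, rel=1e-6)

    def test_regional_ssr_never_exceeds_pooled(self, small_panel):
        d = self._design_with_y(small_panel, {"prev": 0.1, "cons": 0.1}, seed=2)
        het = sc.fit_regional(d)
        assert het.regional_ssr <= het.pooled_ssr + 1e-12

    def test_size_under_homogeneity(self, small_panel):
        rejections = 0
        reps = 40
        for s in range(reps):
            d = self._design_with_y(small_panel, {"prev": 0.104, "cons": 0.113}, seed=100 + s)
            het = sc.fit_regional(d, vary=("prev",))
            rejections += het.p_value < 0.05
        assert rejections / reps <= 0.20

    def test_power_under_heterogeneity(self, small_panel):
        rejections = 0
        reps = 10
        for s in range(reps):
            d = self._design_with_y(small_panel, {"prev": 0.104, "cons": 0.113},
                                    region_bump=0.3, noise=0.02, seed=200 + s)
            het = sc.fit_regional(d, vary=("prev",))
            rejections += het.p_value < 0.05
        assert rejections / reps >= 0.8

    def test_homogeneous_regions_merge_into_few_groups(self, small_panel):
        d = self._design_with_y(small_panel, {"prev": 0.104, "cons": 0.113}, seed=3)
        het = sc.fit_regional(d, vary=("prev",))
        assert len(het.groups) <= 3
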