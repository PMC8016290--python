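import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_flat_panel
from otocarb import lmm, synthetic as syn
from otocarb.params import ConfigurationError, GenerativeParams

WIDTH_SPEC = lmm.ModelSpec(
    response="log_width",
    fixed=("stock", "log_age", "log_age:stock", "tl", "anomt"),
)
D13C_SPEC = lmm.ModelSpec(
    response="d13c",
    fixed=("stock", "age_factor", "age_factor:stock", "tl",
           "year", "year:stock"),
)


def one_way_panel(n_groups=20, m=5, tau=0.4, sigma2=1.0, seed=0):
    """Balanced one-way design on the log-width response."""
    rng = np.random.default_rng(seed)
    panel = make_flat_panel(n_groups, max_age=m + 2)
    d = panel.data
    codes = pd.factorize(d["fish_id"])[0]
    y = 5.0 + np.sqrt(tau) * rng.standard_normal(n_groups)[codes]
    y = y + np.sqrt(sigma2) * rng.standard_normal(len(d))
    d["width_um"] = np.exp(y)
    return panel


def anova_oracle(y, groups):
    """Closed-form balanced one-way REML estimators (MSW, (MSB-MSW)/m)."""
    df = pd.DataFrame({"y": y, "g": groups})
    m = df.groupby("g").size().iloc[0]
    means = df.groupby("g")["y"].mean()
    grand = df["y"].mean()
    a = len(means)
    msb = m * ((means - grand) ** 2).sum() / (a - 1)
    msw = ((df["y"] - means.loc[df["g"]].to_numpy()) ** 2).sum() / (a * (m - 1))
    return msw, (msb - msw) / m


class TestFitLmm:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_one_way_matches_anova_oracle(self, seed):
        panel = one_way_panel(seed=seed)
        rows = panel.analysis
        sigma2_hat, tau_hat = anova_oracle(
            np.log(rows["width_um"].to_numpy()), rows["fish_id"].to_numpy())
        fit = lmm.fit_lmm(
            lmm.ModelSpec(response="log_width", fixed=(), random=("fish",)),
            panel)
        assert fit.sigma2 == pytest.approx(sigma2_hat, rel=1e-6)
        assert fit.tau["fish"] == pytest.approx(tau_hat, rel=1e-6)

    def test_zero_group_structure_degenerate(self):
        rng = np.random.default_rng(4)
        panel = make_flat_panel(500, max_age=12, n_stocks=2)
        panel.data["width_um"] = np.exp(rng.standard_normal(len(panel.data)))
        fit = lmm.fit_lmm(
            lmm.ModelSpec(response="log_width", fixed=()), panel)
        assert fit.tau["fish"] < 0.01 * fit.sigma2
        assert fit.tau["stock_year"] < 0.01 * fit.sigma2

    def test_age_stock_interaction_recovery(self, study_panel, study_env):
        fit = lmm.fit_lmm(WIDTH_SPEC, study_panel, study_env)
        est = fit.coef.loc["log_age_c:stock", "estimate"]
        se = fit.coef.loc["log_age_c:stock", "se"]
        assert abs(est - 0.133) < 3 * se

    def test_variance_component_recovery_averaged(self):
        # study-scale panels simulated at the generative defaults; the
        # averaged estimates must recover each component within 10 %
        taus_f, taus_y, sig = [], [], []
        for seed in range(5):
            params = GenerativeParams(seed=100 + seed)
            panel = syn.generate_cohort(params)
            panel = syn.simulate_d13c_lmm(panel, params)
            fit = lmm.fit_lmm(D13C_SPEC, panel)
            taus_f.append(fit.tau["fish"])
            taus_y.append(fit.tau["stock_year"])
            sig.append(fit.sigma2)
        assert abs(np.mean(taus_f) - 0.128) / 0.128 < 0.10
        assert abs(np.mean(taus_y) - 0.034) / 0.034 < 0.10
        assert abs(np.mean(sig) - 0.144) / 0.144 < 0.10

    def test_singular_design_names_columns(self):
        panel = one_way_panel()
        with pytest.raises(lmm.SingularDesignError, match="stock"):
            lmm.fit_lmm(
                lmm.ModelSpec(response="log_width", fixed=("stock",),
                              random=("fish",)),
                panel)

    def test_too_few_groups_errors(self):
        panel = one_way_panel(n_groups=1)
        with pytest.raises(ConfigurationError, match="fewer than 2"):
            lmm.fit_lmm(
                lmm.ModelSpec(response="log_width", fixed=(), random=("fish",)),
                panel)

    def test_interaction_requires_main_effect(self):
        with pytest.raises(ConfigurationError, match="requires main effect"):
            lmm.ModelSpec(response="d13c", fixed=("year:stock",))


def dummy_fit(loglik=-50.0, p=4, n=100, tau=None, sigma2=1.0, var_fixed=0.0):
    tau = {} if tau is None else tau
    coef = pd.DataFrame({"estimate": np.zeros(p), "se": np.ones(p)},
                        index=[f"b{i}" for i in range(p)])
    return lmm.LMMFit(
        spec=lmm.ModelSpec(response="d13c", fixed=(), random=()),
        coef=coef, vcov=np.eye(p), sigma2=sigma2, tau=tau, loglik=loglik,
        n_obs=n, n_groups={}, converged=True, boundary={},
        var_fixed=var_fixed)


class TestAicc:
    def test_direct_formula(self):
        fit = dummy_fit(loglik=-50.0, p=4, n=100)  # k = 4 + 1 = 5
        assert lmm.aicc(fit) == pytest.approx(110.0 + 60.0 / 94.0, abs=1e-10)

    def test_converges_to_aic_for_large_n(self):
        fit = dummy_fit(loglik=-50.0, p=4, n=10**7)
        aic = -2 * fit.loglik + 2 * fit.n_params
        assert abs(lmm.aicc(fit) - aic) < 1e-4

    @given(k1=st.integers(1, 20), n=st.integers(50, 10_000),
           ll=st.floats(-1e4, 0))
    @settings(max_examples=50, deadline=None)
    def test_penalty_monotone_in_k(self, k1, n, ll):
        f1 = dummy_fit(loglik=ll, p=k1, n=n)
        f2 = dummy_fit(loglik=ll, p=k1 + 1, n=n)
        assert lmm.aicc(f2) > lmm.aicc(f1)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ConfigurationError, match="AICc undefined"):
            lmm.aicc(dummy_fit(p=4, n=6))


class TestIcc:
    def test_fish_icc_from_printed_components(self):
        value = lmm.icc_from_components(
            0.144, {"fish": 0.128, "stock_year": 0.034}, "fish")
        assert round(value, 3) == 0.418

    def test_stockyear_icc_from_printed_components(self):
        value = lmm.icc_from_components(
            0.144, {"fish": 0.128, "stock_year": 0.034}, "stock_year")
        assert round(value, 3) == 0.111

    def test_zero_component(self):
        assert lmm.icc_from_components(1.0, {"fish": 0.0}, "fish") == 0.0

    def test_unknown_term_errors(self):
        with pytest.raises(ConfigurationError, match="unknown random term"):
            lmm.icc_from_components(1.0, {"fish": 0.1}, "year")

    @given(s2=st.floats(0.01, 10), t1=st.floats(0, 10), t2=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_shares_sum_to_one(self, s2, t1, t2):
        tau = {"fish": t1, "stock_year": t2}
        shares = [lmm.icc_from_components(s2, tau, k) for k in tau]
        resid = s2 / (s2 + t1 + t2)
        assert sum(shares) + resid == pytest.approx(1.0, abs=1e-12)


class TestR2:
    def test_formula_identity(self):
        fit = dummy_fit(tau={"fish": 0.3}, sigma2=0.5, var_fixed=0.2)
        r2m, r2c = lmm.r2_nakagawa(fit)
        assert r2m == pytest.approx(0.2)
        assert r2c == pytest.approx(0.5)

    def test_intercept_only_marginal_zero(self):
        panel = one_way_panel()
        fit = lmm.fit_lmm(
            lmm.ModelSpec(response="log_width", fixed=(), random=("fish",)),
            panel)
        r2m, _ = lmm.r2_nakagawa(fit)
        assert r2m == pytest.approx(0.0, abs=1e-12)

    def test_conditional_minus_marginal_tracks_icc_total(self, study_panel):
        fit = lmm.fit_lmm(D13C_SPEC, study_panel)
        r2m, r2c = lmm.r2_nakagawa(fit)
        icc_total = sum(lmm.icc(fit, t) for t in fit.tau)
        # exact relation: the two quantities share vr but use different
        # denominators (with vs without the fixed-effect variance vf), so
        # icc_total = (r2c - r2m) / (1 - r2m)
        assert icc_total == pytest.approx((r2c - r2m) / (1.0 - r2m), abs=1e-10)
        # and they agree approximately when fixed effects explain little
        assert abs((r2c - r2m) - icc_total) < 0.15
        assert r2c >= r2m


class TestYearTrend:
    def _fit_with(self, coefs):
        coef = pd.DataFrame({"estimate": list(coefs.values()),
                             "se": np.ones(len(coefs))},
                            index=list(coefs))
        fit = dummy_fit(p=1)
        fit.coef = coef
        return fit

    def test_icelandic_century_decline(self):
        fit = self._fit_with({"year_c": -0.007, "year_c:stock": 0.004})
        assert lmm.year_trend(fit, "ICE")["per_century"] == pytest.approx(-0.7)

    def test_nea_century_decline(self):
        fit = self._fit_with({"year_c": -0.007, "year_c:stock": 0.004})
        assert lmm.year_trend(fit, "NEA")["per_century"] == pytest.approx(-0.3)

    def test_zero_slope(self):
        fit = self._fit_with({"year_c": 0.0})
        assert lmm.year_trend(fit, "ICE")["per_century"] == 0.0


def _tl_panel(n_fish, beta_tl, seed, tau=0.05, sigma2=0.1):
    rng = np.random.default_rng(seed)
    tl = rng.normal(95, 10, size=n_fish)
    panel = make_flat_panel(n_fish, max_age=6, tl=tl)
    d = panel.data
    codes = pd.factorize(d["fish_id"])[0]
    tl_z = (d["tl_cm"] - panel.centering.tl_mean) / panel.centering.tl_sd
    y = (5.0 + beta_tl * tl_z
         + np.sqrt(tau) * rng.standard_normal(n_fish)[codes]
         + np.sqrt(sigma2) * rng.standard_normal(len(d)))
    d["width_um"] = np.exp(y)
    return panel


class TestFixedEffectTests:
    SPEC = lmm.ModelSpec(response="log_width", fixed=("tl",),
                         random=("fish",))

    def test_null_pvalues_calibrated(self):
        # scaled-down calibration oracle: 300 independent null replicates
        pvals = []
        for seed in range(300):
            fit = lmm.fit_lmm(self.SPEC, _tl_panel(50, 0.0, seed))
            pvals.append(lmm.fixed_effect_tests(fit).loc["tl_z", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_huge_effect_significant(self):
        fit = lmm.fit_lmm(self.SPEC, _tl_panel(50, 3.0, 1))
        assert lmm.fixed_effect_tests(fit).loc["tl_z", "p"] < 0.001

    def test_intercept_only_empty_table(self):
        panel = one_way_panel()
        fit = lmm.fit_lmm(
            lmm.ModelSpec(response="log_width", fixed=(), random=("fish",)),
            panel)
        assert lmm.fixed_effect_tests(fit).empty

    def test_ci_brackets_estimate(self, study_panel, study_env):
        fit = lmm.fit_lmm(WIDTH_SPEC, study_panel, study_env)
        table = lmm.fixed_effect_tests(fit)
        assert (table["ci_low"] <= table["estimate"]).all()
        assert (table["estimate"] <= table["ci_high"]).all()
        assert ((table["df"] >= 1) & (table["df"] <= fit.n_obs)).all()


def _width_panel(seed, zero_anomt=False):
    params = GenerativeParams(
        n_fish={"ICE": 40, "NEA": 40},
        capture_span={"ICE": (1980, 2015), "NEA": (1980, 2015)},
        fish_per_year=3, seed=seed)
    if zero_anomt:
        params.width_model.coefficients["anomt"] = 0.0
    env = syn.simulate_temperature(params)
    panel = syn.generate_cohort(params)
    return syn.simulate_widths(panel, params, env), env


class TestSelectStructure:
    def test_single_candidate_returned_unchanged(self):
        panel, env = _width_panel(seed=2)
        fit, table = lmm.select_structure(
            panel, env, "log_width",
            random_candidates=[("fish", "stock_year")],
            fixed_candidates=[("log_age",)])
        assert fit.spec.random == ("fish", "stock_year")
        assert fit.spec.fixed == ("log_age",)
        assert fit.spec.method == "reml"
        assert len(table) == 2  # one row per phase

    def test_null_sz_term_excluded(self):
        # the generator gives spawning zones zero effect; selection should
        # drop the term
        panel, env = _width_panel(seed=5)
        fit, _ = lmm.select_structure(
            panel, env, "log_width",
            random_candidates=[("fish",), ("fish", "stock_year")],
            fixed_candidates=[("log_age", "sz"), ("log_age",)])
        assert "sz" not in fit.spec.fixed

    def test_null_anomt_selected_in_minority(self):
        # scaled-down consistency check (20 replicates, AnomT effect = 0)
        hits = 0
        for seed in range(20):
            panel, env = _width_panel(seed=300 + seed, zero_anomt=True)
            fit, _ = lmm.select_structure(
                panel, env, "log_width",
                random_candidates=[("fish", "stock_year")],
                fixed_candidates=[("log_age", "anomt"), ("log_age",)])
            hits += "anomt" in fit.spec.fixed
        assert hits < 10

    def test_empty_candidates_error(self, study_panel):
        with pytest.raises(ConfigurationError, match="non-empty"):
            lmm.select_structure(study_panel, None, "log_width",
                                 random_candidates=[], fixed_candidates=[])
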