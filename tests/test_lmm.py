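"""Mixed-model machinery: REML components, tests, Tukey, R^2, VIF."""

import types

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

import seastab as st
from seastab.lmm import CommunityLMM, DesignInfo


def simulate_lmm(n_per_cell=10, site_sd=0.0, resid_sd=1.0, beta_mgmt=0.0,
                 seed=0, n_sites=4):
    rng = np.random.default_rng(seed)
    rows = []
    sites = [f"s{i}" for i in range(n_sites)]
    site_eff = rng.normal(0, site_sd, size=n_sites)
    for i, site in enumerate(sites):
        mgmt = "MPA" if i < n_sites // 2 else "open"
        for season in st.SEASONS:
            for _ in range(n_per_cell):
                y = (site_eff[i] + beta_mgmt * (mgmt == "MPA")
                     + rng.normal(0, resid_sd))
                rows.append({"site": site, "management": mgmt,
                             "season": season, "y": y})
    return pd.DataFrame(rows)


class TestFit:
    def test_zero_site_variance_matches_ols(self):
        data = simulate_lmm(site_sd=0.0, seed=1)
        fit = CommunityLMM.from_dataframe(data, "y").fit()
        di = fit.model.design_info
        x = di.build(data)
        beta_ols = np.linalg.lstsq(x, data["y"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ols, atol=1e-4)

    def test_recovers_group_difference(self):
        data = simulate_lmm(n_per_cell=17, site_sd=0.0, beta_mgmt=1.0, seed=2)
        fit = CommunityLMM.from_dataframe(data, "y",
                                          fixed=("management",)).fit()
        # sum coding: MPA column estimates half the MPA - open difference
        est = 2.0 * fit.params["management[MPA]"]
        se = 2.0 * fit.bse["management[MPA]"]
        assert abs(est - 1.0) < 3 * se

    def test_matches_statsmodels_reml(self):
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        data = simulate_lmm(site_sd=0.7, seed=3)
        fit = CommunityLMM.from_dataframe(data, "y").fit()
        x = fit.model.design_info.build(data)
        ref = sm.MixedLM(data["y"].to_numpy(), x,
                         groups=data["site"].to_numpy()).fit(reml=True)
        assert fit.sigma2_resid == pytest.approx(ref.scale, rel=1e-4)
        assert fit.sigma2_site == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3, abs=1e-6)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.fe_params,
                                   atol=1e-5)

    def test_constant_response_errors(self):
        data = simulate_lmm(seed=4)
        data["y"] = 1.0
        with pytest.raises(ValueError):
            CommunityLMM.from_dataframe(data, "y")

    def test_reml_components_invariant_to_reparameterization(self):
        data = simulate_lmm(site_sd=0.5, seed=5)
        di = DesignInfo.from_dataframe(data, ("season", "management"))
        x_sum = di.build(data)
        # treatment-coded design spanning the same column space
        x_trt = np.column_stack([
            np.ones(len(data)),
            (data["season"] == "LR").to_numpy(float),
            (data["season"] == "D").to_numpy(float),
            (data["management"] == "open").to_numpy(float)])
        fits = [CommunityLMM(data["y"].to_numpy(), x,
                             data["site"].to_numpy()).fit()
                for x in (x_sum, x_trt)]
        assert fits[0].sigma2_site == pytest.approx(fits[1].sigma2_site,
                                                    rel=1e-6, abs=1e-12)
        assert fits[0].sigma2_resid == pytest.approx(fits[1].sigma2_resid,
                                                     rel=1e-6)
        # fitted means agree even though the coefficient bases differ
        np.testing.assert_allclose(fits[0].fittedvalues(),
                                   fits[1].fittedvalues(), atol=1e-6)


def chi2_sf_by_quadrature(x: float, df: int) -> float:
    """Independent chi-square upper tail via numerical integration of the
    density (textbook formula, no scipy.stats)."""
    def pdf(t):
        return (t ** (df / 2 - 1) * np.exp(-t / 2)
                / (2 ** (df / 2) * special.gamma(df / 2)))
    val, _ = integrate.quad(pdf, x, np.inf)
    return val


class TestLRT:
    def test_no_signal_gives_small_chi2(self):
        data = simulate_lmm(site_sd=0.5, seed=6)
        full = CommunityLMM.from_dataframe(data, "y").fit(reml=False)
        null = CommunityLMM.from_dataframe(data, "y", fixed=()).fit(reml=False)
        chi2, df, p = st.lrt_vs_null(full, null)
        assert chi2 >= 0
        assert df == 5
        assert p > 0.01  # no fixed-effect signal was simulated

    @pytest.mark.parametrize("x,df", [(2.7726, 4), (5.9915, 2), (0.5, 1)])
    def test_p_matches_independent_chi2_tail(self, x, df):
        assert stats.chi2.sf(x, df) == pytest.approx(
            chi2_sf_by_quadrature(x, df), abs=1e-8)

    def test_lrt_p_uses_chi2_tail(self):
        data = simulate_lmm(site_sd=0.5, beta_mgmt=0.8, seed=7)
        full = CommunityLMM.from_dataframe(data, "y").fit(reml=False)
        null = CommunityLMM.from_dataframe(data, "y", fixed=()).fit(reml=False)
        chi2, df, p = st.lrt_vs_null(full, null)
        assert p == pytest.approx(chi2_sf_by_quadrature(chi2, df), abs=1e-8)

    def test_requires_ml(self):
        data = simulate_lmm(seed=8)
        full = CommunityLMM.from_dataframe(data, "y").fit(reml=True)
        null = CommunityLMM.from_dataframe(data, "y", fixed=()).fit(reml=False)
        with pytest.raises(ValueError):
            st.lrt_vs_null(full, null)

    def test_non_nested_rejected(self):
        data = simulate_lmm(seed=9)
        a = CommunityLMM.from_dataframe(data, "y", fixed=("season",)).fit(reml=False)
        b = CommunityLMM.from_dataframe(data, "y", fixed=("management",)).fit(reml=False)
        with pytest.raises(ValueError):
            st.lrt_vs_null(a, b)


class TestNakagawaR2:
    def _stub(self, var_fixed, s_site, s_res):
        fitted = np.array([0.0, 2.0]) * np.sqrt(var_fixed)  # var (ddof=0) = var_fixed
        stub = types.SimpleNamespace(
            fittedvalues=lambda: fitted, sigma2_site=s_site,
            sigma2_resid=s_res)
        return stub

    def test_hand_formula(self):
        r2m, r2c = st.nakagawa_r2(self._stub(1.0, 1.0, 2.0))
        assert (r2m, r2c) == (0.25, 0.5)

    def test_no_fixed_effects(self):
        r2m, r2c = st.nakagawa_r2(self._stub(0.0, 1.0, 1.0))
        assert r2m == 0.0 and r2c == 0.5

    def test_zero_site_variance_equalizes(self):
        r2m, r2c = st.nakagawa_r2(self._stub(1.0, 0.0, 1.0))
        assert r2m == r2c

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            st.nakagawa_r2(self._stub(0.0, 0.0, 0.0))

    def test_ordering_on_real_fit(self):
        data = simulate_lmm(site_sd=0.5, beta_mgmt=0.5, seed=10)
        fit = CommunityLMM.from_dataframe(data, "y").fit()
        r2m, r2c = st.nakagawa_r2(fit)
        assert 0 <= r2m <= r2c <= 1


def studentized_range_sf_by_quadrature(q: float, k: int, df: float) -> float:
    """Independent tail probability of the studentized range by direct
    double integration of its classical representation."""
    def range_cdf(x):
        f = lambda u: stats.norm.pdf(u) * (
            stats.norm.cdf(u) - stats.norm.cdf(u - x)) ** (k - 1)
        val, _ = integrate.quad(f, -np.inf, np.inf)
        return k * val

    def s_pdf(s):
        return (2.0 * (df / 2.0) ** (df / 2.0) / special.gamma(df / 2.0)
                * s ** (df - 1) * np.exp(-df * s * s / 2.0))

    val, _ = integrate.quad(lambda s: s_pdf(s) * range_cdf(q * s), 0, np.inf,
                            limit=200)
    return 1.0 - val


class TestTukey:
    def test_three_level_factor_gives_three_contrasts(self):
        data = simulate_lmm(site_sd=0.3, seed=11)
        fit = CommunityLMM.from_dataframe(data, "y").fit()
        tk = fit.tukey("season")
        assert len(tk) == 3
        assert set(tk["contrast"]) == {"SR-LR", "SR-D", "LR-D"}

    def test_balanced_case_matches_integration_oracle(self):
        data = simulate_lmm(n_per_cell=8, site_sd=0.4, seed=12)
        fit = CommunityLMM.from_dataframe(data, "y",
                                          fixed=("season",)).fit()
        tk = fit.tukey("season")
        assert tk.attrs["method"] == "studentized-range"
        for _, row in tk.iterrows():
            ref = studentized_range_sf_by_quadrature(
                abs(row["t"]) * np.sqrt(2.0), 3, row["df"])
            assert row["p_adjusted"] == pytest.approx(ref, abs=1e-6)

    def test_identical_level_means_give_zero_contrasts_p_one(self):
        # noiseless data whose season means are exactly equal: y varies
        # only with site, symmetrically within each management level
        data = simulate_lmm(site_sd=0.0, resid_sd=1.0, seed=13)
        site_vals = {"s0": 1.0, "s1": -1.0, "s2": 1.0, "s3": -1.0}
        data["y"] = data["site"].map(site_vals)
        fit = CommunityLMM.from_dataframe(data, "y", fixed=("season",)).fit()
        tk = st.tukey_pairs(fit, "season")
        np.testing.assert_allclose(tk["estimate"], 0.0, atol=1e-12)
        np.testing.assert_allclose(tk["p_adjusted"], 1.0)

    def test_interaction_dissection_within_level(self):
        data = simulate_lmm(site_sd=0.3, seed=14)
        fit = CommunityLMM.from_dataframe(data, "y").fit()
        tk = fit.tukey("season", within={"management": "MPA"})
        assert tk.attrs["within"] == {"management": "MPA"}
        assert len(tk) == 3

    def test_unknown_factor_errors(self):
        data = simulate_lmm(seed=15)
        fit = CommunityLMM.from_dataframe(data, "y").fit()
        with pytest.raises(KeyError):
            fit.tukey("depth")


class TestVif:
    def test_orthogonal_predictors(self):
        x = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        out = st.vif(x)
        np.testing.assert_allclose(out.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_known_correlation(self):
        # unit-norm orthogonal basis -> sample R^2 exactly 0.64
        u = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
        v = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0
        x = pd.DataFrame({"a": u, "b": 0.8 * u + 0.6 * v})
        out = st.vif(x)
        np.testing.assert_allclose(out.to_numpy(), [1 / 0.36, 1 / 0.36],
                                   rtol=1e-9)
        assert out["a"] == pytest.approx(2.7778, abs=1e-4)

    def test_duplicated_column_is_infinite(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4],
                          "c": [4.0, 1, 2, 2]})
        out = st.vif(x)
        assert np.isinf(out["a"]) and np.isinf(out["b"])
        assert np.isfinite(out["c"])

    def test_constant_column_errors(self):
        with pytest.raises(ValueError):
            st.vif(pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]}))
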