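"""Synthetic survey generator: design arithmetic, determinism, ground truth."""

import io

import numpy as np
import pytest
from scipy import stats

import seastab as st
from seastab.simulate import expected_cover
from seastab.survey import write_survey_csv


def _survey_bytes(records) -> bytes:
    fish, cover = io.StringIO(), io.StringIO()
    write_survey_csv(records, fish, cover)
    return (fish.getvalue() + cover.getvalue()).encode()


class TestDesign:
    def test_default_design_counts(self, survey):
        assert len(survey) == 111
        by_mgmt = {}
        for rec in survey:
            by_mgmt[rec.management] = by_mgmt.get(rec.management, 0) + 1
        assert by_mgmt == {"MPA": 51, "open": 60}

    def test_quadrats_per_transect(self, survey):
        for rec in survey:
            assert len(rec.quadrat_cover_pct) == 6
            assert all(c % 10 == 0 and 0 <= c <= 100
                       for c in rec.quadrat_cover_pct)

    def test_lengths_on_grid(self, survey):
        for rec in survey:
            for obs in rec.fish:
                assert obs.length_cm % 5 == 0 and obs.length_cm > 0

    def test_same_seed_is_byte_identical(self, default_config):
        a = st.generate_survey(default_config)
        b = st.generate_survey(default_config)
        assert _survey_bytes(a) == _survey_bytes(b)

    def test_different_seed_differs(self, default_config, survey):
        other = st.generate_survey(default_config.replace(seed=8))
        assert _survey_bytes(other) != _survey_bytes(survey)

    def test_config_round_trip(self, default_config, tmp_path):
        default_config.to_json(tmp_path / "cfg.json")
        back = st.GeneratorConfig.from_json(tmp_path / "cfg.json")
        assert back.species == default_config.species
        np.testing.assert_allclose(back.alpha, default_config.alpha)
        assert back.design.sites == default_config.design.sites

    def test_invalid_config_rejected(self, default_config):
        with pytest.raises(ValueError):
            default_config.replace(theta=0.0)
        with pytest.raises(ValueError):
            default_config.replace(fishing_phi={"MPA": 0.0, "open": -1.0})


class TestNullScenario:
    def test_seasonal_equality_rarely_rejected_under_null(self):
        """Without any seasonal structure, per-species season differences
        are sampling noise: an ANOVA across seasons should not reject for
        ~95% of species-survey combinations."""
        cfg = st.GeneratorConfig.null_scenario(n_species=8, n_families=3)
        n_surveys, rejections, total = 25, 0, 0
        for s in range(n_surveys):
            recs = st.generate_survey(cfg.replace(seed=1000 + s))
            table = st.aggregate_density(recs, "transect")
            frame = table.to_frame()
            for sp in table.species:
                groups = [g[sp].to_numpy()
                          for _, g in frame.groupby("season")]
                _, p = stats.f_oneway(*groups)
                total += 1
                rejections += p < 0.05
        assert rejections / total <= 0.10


class TestGroundTruth:
    def test_flat_expectation_without_forcing(self):
        cfg = st.GeneratorConfig.null_scenario(n_species=5, n_families=2,
                                               beta_veg_mean=0.0,
                                               beta_veg_sd=0.0)
        truth = st.ground_truth(cfg)["density"]
        for (site, sp), grp in truth.groupby(["site", "species"]):
            np.testing.assert_allclose(grp["expected_density"],
                                       grp["expected_density"].iloc[0])
            i = cfg.species.index(sp)
            expected = np.exp(cfg.alpha[i] + cfg.site_effect[site])
            np.testing.assert_allclose(grp["expected_density"], expected)

    def test_log_linearity_of_season_multiplier(self, default_config):
        cfg = default_config
        bumped = cfg.replace(
            season_response=cfg.season_response + np.array([np.log(2), 0, 0]))
        t0 = st.ground_truth(cfg)["density"].set_index(
            ["site", "season", "species"])["expected_density"]
        t1 = st.ground_truth(bumped)["density"].set_index(
            ["site", "season", "species"])["expected_density"]
        ratio = (t1 / t0).reset_index()
        sr = ratio[ratio["season"] == "SR"]["expected_density"]
        rest = ratio[ratio["season"] != "SR"]["expected_density"]
        np.testing.assert_allclose(sr, 2.0)
        np.testing.assert_allclose(rest, 1.0)

    def test_expectations_match_simulation(self):
        """Empirical site x season x species means over replicate surveys
        agree with the closed-form expectations within Monte-Carlo error."""
        cfg = st.GeneratorConfig.default(n_species=6, n_families=2)
        n_rep = 80
        sums = None
        sumsq = None
        n_per_cell = None
        for s in range(n_rep):
            recs = st.generate_survey(cfg.replace(seed=5000 + s))
            tab = st.aggregate_density(recs, "transect")
            grp = tab.to_frame().groupby(["site", "season"])[tab.species]
            m = grp.mean()
            if sums is None:
                sums, sumsq = m * 0.0, m * 0.0
                n_per_cell = grp.size()
            sums += m
            sumsq += m ** 2
        emp_mean = sums / n_rep
        truth = st.ground_truth(cfg)["density"].pivot_table(
            index=["site", "season"], columns="species",
            values="expected_density")[list(emp_mean.columns)]
        # MC standard error of the replicate-mean of per-cell means
        var_between = (sumsq / n_rep - emp_mean ** 2) * n_rep / (n_rep - 1)
        se = np.sqrt(var_between / n_rep)
        z = (emp_mean - truth).abs() / se.clip(lower=1e-9)
        # 3 MC standard errors, with the generator's small cover-noise
        # second-order term absorbed by the >=3se band
        assert (z.to_numpy() <= 3.0).mean() > 0.97
        assert np.median(z.to_numpy()) < 1.5


class TestStructuralContrasts:
    def test_cover_more_variable_in_open_sites(self, default_config):
        """amp_open > amp_MPA: seasonal variance of site-mean cover is
        larger outside protection (in the deterministic expectation and in
        a realized survey)."""
        exp = expected_cover(default_config)
        var = exp.groupby(["management", "site"])["cover_pct"].var()
        assert var["open"].min() > var["MPA"].max()
        recs = st.generate_survey(default_config)
        obs = st.cover_table(recs, level="site")
        ovar = obs.groupby(["management", "site"])["cover_pct"].var()
        assert ovar["open"].mean() > ovar["MPA"].mean()

    def test_large_theta_approaches_poisson(self):
        cfg = st.GeneratorConfig.null_scenario(
            n_species=4, n_families=2, theta=5e4,
            beta_veg_mean=0.0, beta_veg_sd=0.0)
        recs = st.generate_survey(cfg)
        tab = st.aggregate_density(recs, "transect")
        frame = tab.to_frame()
        ratios = []
        for (site, season), g in frame.groupby(["site", "season"]):
            for sp in tab.species:
                v = g[sp].to_numpy()
                if v.mean() > 1:
                    ratios.append(v.var(ddof=1) / v.mean())
        assert 0.6 < np.median(ratios) < 1.6

    def test_counts_are_nonnegative_integers(self, transect_table):
        vals = transect_table.values.to_numpy()
        assert (vals >= 0).all()
        np.testing.assert_allclose(vals, np.round(vals))
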