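"""Piecewise SEM: basis sets, Fisher's C, path fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hs


import seastab as st


def make_sem_data(seed=0, n_sites=4, n_per_cell=10, beta_cover=0.7,
                  direct_season=0.0, site_sd=0.3):
    """Transect-style data where season drives cover and cover (and
    optionally season directly) drives fish density."""
    rng = np.random.default_rng(seed)
    rows = []
    season_cover = {"SR": 1.0, "LR": -1.0, "D": 0.0}
    for i in range(n_sites):
        site_eff = rng.normal(0, site_sd)
        for season in st.SEASONS:
            for _ in range(n_per_cell):
                cover = season_cover[season] + rng.normal(0, 0.5)
                density = (site_eff + beta_cover * cover
                           + direct_season * season_cover[season]
                           + rng.normal(0, 0.5))
                rows.append({"site": f"s{i}", "management": "open",
                             "season": season, "cover": cover,
                             "density": density})
    return pd.DataFrame(rows)


class TestBasisSet:
    def test_chain_gives_single_claim(self):
        m = st.PathModel(nodes=["x", "y", "z"],
                         edges=[("x", "y"), ("y", "z")], composites=())
        claims = st.basis_set(m)
        assert len(claims) == 1
        c = claims[0]
        assert (c.x, c.y, c.conditioning) == ("x", "z", ("y",))

    def test_fully_connected_dag_is_saturated(self):
        m = st.PathModel(nodes=["a", "b", "c"],
                         edges=[("a", "b"), ("a", "c"), ("b", "c")],
                         composites=())
        assert st.basis_set(m) == []
        c, df, p = st.fishers_c([])
        assert (c, df, p) == (0.0, 0, 1.0)

    def test_mediation_model_matches_hand_enumeration(self):
        m = st.PathModel.seagrass_mediation("density", direct=False)
        claims = st.basis_set(m)
        assert len(claims) == 1
        assert claims[0].x == "season"
        assert claims[0].y == "density"
        assert claims[0].conditioning == ("cover",)

    def test_direct_model_is_saturated(self):
        m = st.PathModel.seagrass_mediation("density", direct=True)
        assert st.basis_set(m) == []

    def test_invariant_to_node_listing_order(self):
        edges = [("x", "y"), ("y", "z"), ("x", "w")]
        a = st.PathModel(nodes=["x", "y", "z", "w"], edges=edges, composites=())
        b = st.PathModel(nodes=["w", "z", "y", "x"], edges=edges, composites=())
        assert [str(c) for c in st.basis_set(a)] == \
               [str(c) for c in st.basis_set(b)]

    def test_cyclic_graph_rejected(self):
        with pytest.raises(ValueError):
            st.PathModel(nodes=["x", "y"], edges=[("x", "y"), ("y", "x")],
                         composites=())

    def test_composite_must_be_exogenous(self):
        with pytest.raises(ValueError):
            st.PathModel(nodes=["season", "cover"],
                         edges=[("cover", "season")])


class TestFishersC:
    def test_all_p_one(self):
        c, df, p = st.fishers_c([1.0, 1.0, 1.0])
        assert c == 0.0 and df == 6 and p == 1.0

    def test_two_half_pvalues(self):
        c, df, p = st.fishers_c([0.5, 0.5])
        assert c == pytest.approx(2.7726, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.5966, abs=1e-4)

    def test_single_p05_identity(self):
        # C = -2 ln 0.05 and the chi^2_2 tail at that point is 0.05 again
        c, df, p = st.fishers_c([0.05])
        assert c == pytest.approx(5.9915, abs=1e-4)
        assert df == 2
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            st.fishers_c([0.0, 0.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hs.lists(hs.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=8))
    def test_permutation_invariance_and_monotonicity(self, ps):
        c1, df1, p1 = st.fishers_c(ps)
        c2, df2, p2 = st.fishers_c(list(reversed(ps)))
        assert c1 == pytest.approx(c2) and df1 == df2
        smaller = [ps[0] * 0.5] + ps[1:]
        c3, _, p3 = st.fishers_c(smaller)
        assert c3 > c1 - 1e-12
        assert p3 <= p1 + 1e-12


class TestFitPsem:
    def test_deterministic_path_standardizes_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        data = pd.DataFrame({"x": x, "y": 3.0 * x,
                             "site": ["a", "b"] * 20})
        m = st.PathModel(nodes=["x", "y"], edges=[("x", "y")], composites=())
        res = st.fit_psem(m, data)
        assert res.paths.iloc[0]["std_coef"] == pytest.approx(1.0, abs=1e-9)
        assert res.df == 0 and res.pvalue == 1.0

    def test_indirect_topology_recovered_on_one_replicate(self):
        data = make_sem_data(seed=1, beta_cover=0.7, direct_season=0.0)
        m = st.PathModel.seagrass_mediation("density", direct=False)
        res = st.fit_psem(m, data)
        paths = res.paths.set_index("predictor")
        assert paths.loc["cover", "p"] < 0.05
        assert res.claims.iloc[0]["p"] > 0.05    # no direct season effect
        assert res.accepted

    def test_missing_direct_path_detected(self):
        data = make_sem_data(seed=2, beta_cover=0.4, direct_season=1.0)
        m = st.PathModel.seagrass_mediation("density", direct=False)
        res = st.fit_psem(m, data)
        assert res.claims.iloc[0]["p"] < 0.05
        assert not res.accepted

    def test_season_coefficients_flagged_uninterpretable(self):
        data = make_sem_data(seed=3)
        m = st.PathModel.seagrass_mediation("density", direct=False)
        res = st.fit_psem(m, data)
        season_rows = res.paths[res.paths["response"] == "cover"]
        assert (~season_rows["sign_interpretable"]).all()
        assert res.r2_conditional.keys() == {"cover", "density"}

    def test_management_subset(self):
        data = make_sem_data(seed=4)
        data.loc[:10, "management"] = "MPA"
        m = st.PathModel.seagrass_mediation("density", direct=False)
        with pytest.raises(ValueError):
            st.PiecewiseSEM(m, data, management_subset="reserve")
        res = st.fit_psem(m, data, management_subset="open")
        assert res.node_results["density"].nobs == (data["management"]
                                                    == "open").sum()

    def test_unidentifiable_node_names_node(self):
        data = make_sem_data(seed=5)
        data["density"] = 1.0
        m = st.PathModel.seagrass_mediation("density", direct=False)
        with pytest.raises(ValueError, match="density"):
            st.fit_psem(m, data)

    def test_json_round_trip(self, tmp_path):
        m = st.PathModel.seagrass_mediation("density", direct=False)
        m.to_json(tmp_path / "model.json")
        back = st.PathModel.from_json(tmp_path / "model.json")
        assert back.nodes == m.nodes and back.edges == m.edges

    def test_standardization_identity(self):
        """Standardized coefficient equals the raw coefficient after
        z-scoring both variables."""
        data = make_sem_data(seed=6)
        m = st.PathModel(nodes=["cover", "density"],
                         edges=[("cover", "density")], composites=())
        res = st.fit_psem(m, data)
        zdata = data.copy()
        for c in ("cover", "density"):
            zdata[c] = (data[c] - data[c].mean()) / data[c].std(ddof=1)
        zres = st.fit_psem(m, zdata)
        assert res.paths.iloc[0]["std_coef"] == pytest.approx(
            zres.paths.iloc[0]["coef"], abs=1e-9)
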