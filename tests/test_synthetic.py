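"""Generator tests: determinism, structural invariants, and the statistical
properties the simulated data must carry for recovery experiments."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import geopoisson as gp
from geopoisson import synthetic
from geopoisson.synthetic import ConfigurationError, FeasibilityError, joint_from_or
from geopoisson.types import ETHNIC_COLUMNS


class TestGeography:
    def test_counts_and_hierarchy(self):
        geo = gp.generate_geography(51, 61, seed=0)
        assert geo.n_states == 51
        assert geo.n_counties == 3111
        assert set(geo.counties["state_id"]) <= set(geo.states["state_id"])

    def test_single_county(self):
        geo = gp.generate_geography(1, 1, seed=0)
        assert geo.n_counties == 1 and geo.n_states == 1

    def test_range_draws_counties_per_state(self):
        geo = gp.generate_geography(20, (3, 9), seed=4)
        per = geo.counties.groupby("state_id").size()
        assert per.between(3, 9).all()
        assert per.nunique() > 1

    def test_deterministic_for_seed(self):
        a = gp.generate_geography(8, (2, 6), seed=11)
        b = gp.generate_geography(8, (2, 6), seed=11)
        pd.testing.assert_frame_equal(a.states, b.states)
        pd.testing.assert_frame_equal(a.counties, b.counties)
        c = gp.generate_geography(8, (2, 6), seed=12)
        assert not a.counties.equals(c.counties)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            gp.generate_geography(0, 5, seed=0)
        with pytest.raises(ConfigurationError):
            gp.generate_geography(3, (5, 2), seed=0)
        with pytest.raises(ConfigurationError):
            gp.generate_geography(3, 5, pop_distribution={"median": -1}, seed=0)


class TestCovariates:
    def test_invariants_at_paper_scale(self, paper_scale):
        covars = paper_scale["covars"]
        covars.validate()
        eth = covars.data[list(ETHNIC_COLUMNS)].sum(axis=1)
        assert (eth <= 100 + 1e-9).all()

    def test_point_mass_config_gives_constant_columns(self):
        geo = gp.generate_geography(3, 4, seed=2)
        covars = gp.generate_covariates(
            geo, config={"Income": {"dist": "constant", "value": 50.0},
                         "Urban": {"dist": "constant", "value": 40.0}}, seed=2)
        assert covars.data["Income"].nunique() == 1
        assert covars.data["Urban"].nunique() == 1

    def test_male_genital_malformation_tail_reaches_published_maximum(self, paper_scale):
        """Default right-skewed config: county max near 2.4%, mean near 0.27%."""
        x = paper_scale["covars"].data["ConGenM"]
        assert 1.5 < x.max() < 6.0
        assert 0.2 < x.mean() < 0.35

    def test_determinism(self):
        geo = gp.generate_geography(4, 4, seed=5)
        a = gp.generate_covariates(geo, seed=6)
        b = gp.generate_covariates(geo, seed=6)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestSimulatePanel:
    def test_row_count_and_structure(self, paper_scale):
        panel = paper_scale["panel"]
        assert len(panel.data) == 3111 * 2 * 2
        assert set(panel.data["disease"]) == {"ASD", "ID"}

    def test_determinism(self):
        geo = gp.generate_geography(3, 5, seed=1)
        covars = gp.generate_covariates(geo, seed=1)
        a, ra = gp.simulate_panel(geo, covars, seed=9)
        b, rb = gp.simulate_panel(geo, covars, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ra.v_county, rb.v_county)

    def test_zero_population_cells_have_zero_counts(self):
        geo = gp.generate_geography(2, 3, seed=3)
        geo.counties.loc[0, "pop_male"] = 0
        covars = gp.generate_covariates(geo, seed=3)
        panel, _ = gp.simulate_panel(geo, covars, seed=3)
        cid = geo.counties.loc[0, "county_id"]
        rows = panel.data.query("county_id == @cid and gender == 'M'")
        assert (rows["y"] == 0).all()

    def test_mean_rate_matches_intercept_in_degenerate_limit(self):
        """b = 0, zero-variance effects, intercept log(0.001): the empirical
        mean of y/N converges to 0.001 (law of large numbers, 3 SE)."""
        n = 25_000
        geo = gp.generate_geography(
            1, n, pop_distribution={"dist": "constant", "value": 2000}, seed=7)
        covars = gp.generate_covariates(geo, seed=7)
        spec = gp.ModelSpec()
        b = synthetic.default_parameters(spec).b.copy()
        b[:] = 0.0
        b["ASD:Intercept"] = np.log(0.001)
        b["ID:Intercept"] = np.log(0.001)
        params = gp.ParameterSet(b=b, sigma_state=np.zeros((2, 2)),
                                 sigma_county=np.zeros((2, 2)))
        panel, _ = gp.simulate_panel(geo, covars, params, spec, seed=8)
        rates = panel.data["y"] / panel.data["N"]
        # each cell contributes Poisson(N * 0.001) / N
        se = np.sqrt(0.001 / (2000 * len(panel.data)))
        assert abs(rates.mean() - 0.001) < 3 * se

    def test_state_effect_correlation_matches_specification(self):
        """Published state covariance (2.666, correlation 0.974): the sample
        correlation of the drawn state effects agrees within 3 SE."""
        geo = gp.generate_geography(
            600, 1, pop_distribution={"dist": "constant", "value": 50}, seed=13)
        covars = gp.generate_covariates(geo, seed=13)
        params = synthetic.default_parameters()
        b = params.b.copy()
        b[:] = 0.0
        b["ASD:Intercept"] = b["ID:Intercept"] = -14.0  # keep all rates tiny
        params = gp.ParameterSet(b=b, sigma_state=params.sigma_state,
                                 sigma_county=np.zeros((2, 2)))
        _, raneff = gp.simulate_panel(geo, covars, params, seed=13)
        r = np.corrcoef(raneff.v_state.to_numpy().T)[0, 1]
        se = (1 - 0.974 ** 2) / np.sqrt(600)
        assert abs(r - 0.974) < 3 * se

    def test_county_effect_covariance_converges(self):
        geo = gp.generate_geography(
            2, 2000, pop_distribution={"dist": "constant", "value": 50}, seed=14)
        covars = gp.generate_covariates(geo, seed=14)
        base = synthetic.default_parameters()
        b = base.b.copy()
        b[:] = 0.0
        b["ASD:Intercept"] = b["ID:Intercept"] = -14.0
        params = gp.ParameterSet(b=b, sigma_state=np.zeros((2, 2)),
                                 sigma_county=base.sigma_county)
        _, raneff = gp.simulate_panel(geo, covars, params, seed=14)
        S = np.cov(raneff.v_county.to_numpy().T)
        target = params.sigma_county
        # variance of a sample covariance entry ~ (s_ii s_jj + s_ij^2)/n
        for i in range(2):
            for j in range(2):
                se = np.sqrt((target[i, i] * target[j, j] + target[i, j] ** 2) / 4000)
                assert abs(S[i, j] - target[i, j]) < 3 * se

    def test_glm_recovers_weights_in_zero_variance_limit(self):
        """With variances -> 0 the panel is a plain Poisson GLM: regression
        recovers the generating weights within 3 SE at 3,000 counties."""
        geo = gp.generate_geography(
            10, 300, pop_distribution={"dist": "constant", "value": 40_000},
            seed=21)
        covars = gp.generate_covariates(geo, seed=21)
        spec = gp.ModelSpec(covariates={
            "ASD": ("Gender", "Income", "Urban", "ConGenM", "Viral_M"),
            "ID": ("Gender", "Income", "Urban", "ConGenM", "Viral_M"),
        })
        b = pd.Series({
            "ASD:Intercept": -7.2, "ASD:Gender": -0.699367, "ASD:Income": 0.032,
            "ASD:Urban": 0.036, "ASD:ConGenM": 1.345, "ASD:Viral_M": 0.18,
            "ID:Intercept": -7.8, "ID:Gender": -0.114, "ID:Income": 0.027,
            "ID:Urban": 0.031, "ID:ConGenM": 0.66, "ID:Viral_M": 0.211,
        })
        params = gp.ParameterSet(b=b, sigma_state=np.zeros((2, 2)),
                                 sigma_county=np.zeros((2, 2)))
        panel, _ = gp.simulate_panel(geo, covars, params, spec, seed=22)
        design = gp.build_design(panel, covars, geo, spec)
        fit = sm.GLM(design.y, design.X, family=sm.families.Poisson(),
                     offset=np.log(design.N)).fit()
        z = np.abs(fit.params - design.b_vector(params)) / fit.bse
        assert np.mean(z < 3) >= 0.95


class TestPatients:
    def _simple_panel(self, n, p_asd, p_cg):
        geo = gp.generate_geography(
            1, 1, pop_distribution={"dist": "constant", "value": n}, seed=0)
        covars = gp.generate_covariates(
            geo, config={"ConGenM": {"dist": "constant", "value": 100 * p_cg},
                         "ConGenF": {"dist": "constant", "value": 100 * p_cg}},
            seed=0)
        cid = geo.counties.loc[0, "county_id"]
        panel = gp.IncidencePanel(pd.DataFrame([
            {"county_id": cid, "disease": "ASD", "gender": "M",
             "y": int(n * p_asd), "N": n},
            {"county_id": cid, "disease": "ID", "gender": "M",
             "y": int(n * p_asd / 4), "N": n},
        ]))
        return panel, covars

    def test_joint_from_or_matches_numeric_solution(self):
        from scipy.optimize import brentq
        for p1, p2, psi in [(0.01, 0.003, 5.53), (0.3, 0.2, 0.25), (0.05, 0.5, 2.0)]:
            cells = joint_from_or(p1, p2, psi)
            # independent numeric solve of p11 from the odds-ratio equation
            def f(p11):
                return (p11 * (1 - p1 - p2 + p11)
                        - psi * (p1 - p11) * (p2 - p11))
            lo = max(0.0, p1 + p2 - 1) + 1e-12
            hi = min(p1, p2) - 1e-12
            p11 = brentq(f, lo, hi, xtol=1e-15)
            assert cells[0] == pytest.approx(p11, abs=1e-10)
            assert cells.sum() == pytest.approx(1.0, abs=1e-12)

    def test_independence_when_target_or_is_one(self):
        panel, covars = self._simple_panel(200_000, 0.01, 0.01)
        pats = gp.generate_patients(panel, covars, target_or=1.0, seed=5)
        res = gp.comorbidity_or(pats)
        assert 0.7 < res["odds_ratio"] < 1.4

    def test_fisher_estimate_near_target_at_one_million_males(self):
        panel, covars = self._simple_panel(1_000_000, 0.01, 0.003)
        pats = gp.generate_patients(panel, covars, target_or=5.53, seed=6)
        res = gp.comorbidity_or(pats, stratum={"gender": "M"})
        a, b = res["table"][0]
        c, d = res["table"][1]
        se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(np.log(res["odds_ratio"]) - np.log(5.53)) < 3 * se_log

    def test_zero_prevalence_county_yields_no_flags(self):
        panel, covars = self._simple_panel(10_000, 0.0, 0.0)
        pats = gp.generate_patients(panel, covars, target_or=5.53, seed=7)
        assert not pats.data["flag_ASD"].any()
        assert not pats.data["flag_ConGen"].any()

    def test_invalid_target_or_raises_with_range(self):
        panel, covars = self._simple_panel(1000, 0.01, 0.01)
        with pytest.raises(FeasibilityError, match=r"\(0, inf\)"):
            gp.generate_patients(panel, covars, target_or=-2.0, seed=0)
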