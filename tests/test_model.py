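"""Design construction, likelihood, marginalisation and transform tests,
each checked against an independent oracle or a published identity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

import geopoisson as gp
from geopoisson import model as gmodel
from geopoisson.types import SchemaError, ValidationError

from conftest import make_single_cell, trapezoid_marginal


@pytest.fixture(scope="module")
def small_instance():
    """3 states x 3 counties, 2 covariates per disease, with known params."""
    geo = gp.generate_geography(
        3, 3, pop_distribution={"dist": "constant", "value": 1_000_000}, seed=5)
    covars = gp.generate_covariates(geo, seed=5)
    spec = gp.ModelSpec(covariates={"ASD": ("Gender", "Income"),
                                    "ID": ("Gender", "Income")})
    params = gp.ParameterSet(
        b=pd.Series({"ASD:Intercept": -6.5, "ASD:Gender": -0.7,
                     "ASD:Income": 0.02, "ID:Intercept": -7.0,
                     "ID:Gender": -0.1, "ID:Income": 0.01}),
        sigma_state=[[0.3, 0.2], [0.2, 0.3]],
        sigma_county=[[0.4, 0.3], [0.3, 0.4]],
    )
    panel, raneff = gp.simulate_panel(geo, covars, params, spec, seed=5)
    design = gp.build_design(panel, covars, geo, spec)
    return design, params, raneff, panel, covars, geo, spec


class TestBuildDesign:
    def test_paper_scale_dimensions(self, paper_scale):
        design = paper_scale["design"]
        assert design.X.shape == (12_444, 44)
        assert design.n_counties == 3111
        assert design.n_states == 51

    def test_centered_columns_have_zero_mean(self, paper_scale):
        X = paper_scale["design"].X
        intercepts = [i for i, lbl in enumerate(paper_scale["design"].col_labels)
                      if lbl.endswith("Intercept")]
        centered = np.delete(np.arange(X.shape[1]), intercepts)
        assert np.abs(X[:, centered].mean(axis=0)).max() < 1e-10

    def test_single_county_maps_all_rows_to_one_unit(self):
        geo = gp.generate_geography(1, 1, seed=2)
        covars = gp.generate_covariates(geo, seed=2)
        panel, _ = gp.simulate_panel(geo, covars, seed=2)
        design = gp.build_design(panel, covars, geo)
        assert design.n_rows == 4
        assert set(design.row_county) == {0}
        assert set(design.row_state) == {0}

    def test_missing_covariate_column_named_in_error(self, small_instance):
        design, params, raneff, panel, covars, geo, spec = small_instance
        bad = gp.ModelSpec(covariates={"ASD": ("Gender", "NoSuchColumn"),
                                       "ID": ("Gender",)})
        with pytest.raises(SchemaError, match="NoSuchColumn"):
            gp.build_design(panel, covars, geo, bad)

    def test_zero_offset_rows_dropped_with_warning(self):
        geo = gp.generate_geography(2, 2, seed=3)
        geo.counties.loc[0, "pop_female"] = 0
        covars = gp.generate_covariates(geo, seed=3)
        panel, _ = gp.simulate_panel(geo, covars, seed=3)
        with pytest.warns(UserWarning, match="zero-offset"):
            design = gp.build_design(panel, covars, geo)
        assert design.n_rows == 2 * 2 * 2 * 2 - 2

    def test_eval_reference_level_cannot_be_requested(self, small_instance):
        design, params, raneff, panel, covars, geo, spec = small_instance
        bad = gp.ModelSpec(covariates={"ASD": ("Eval-2",), "ID": ("Gender",)})
        with pytest.raises(SchemaError, match="reference"):
            gp.build_design(panel, covars, geo, bad)


class TestLinearPredictor:
    def test_zero_everything_gives_zero(self, small_instance):
        design, params, raneff, *_ = small_instance
        zero = gp.ParameterSet(b=params.b * 0, sigma_state=params.sigma_state,
                               sigma_county=params.sigma_county)
        z_re = gp.RandomEffects(v_state=raneff.v_state * 0,
                                v_county=raneff.v_county * 0)
        assert np.allclose(gp.linear_predictor(design, zero, z_re), 0.0)

    def test_state_county_cancellation(self):
        design, params = make_single_cell(1, 1000, 0.5, 0.5, np.log(0.001))
        raneff = gp.RandomEffects(
            v_state=pd.DataFrame({"ASD": [0.5]}, index=["S01"]),
            v_county=pd.DataFrame({"ASD": [-0.5]}, index=["S01C1"]))
        eta = gp.linear_predictor(design, params, raneff)
        assert eta == pytest.approx([np.log(0.001)], abs=1e-14)

    def test_matches_row_by_row_oracle(self, small_instance):
        design, params, raneff, *_ = small_instance
        eta = gp.linear_predictor(design, params, raneff)
        b = design.b_vector(params)
        vs, vc = design.raneff_arrays(raneff)
        for r in range(design.n_rows):  # brute-force per-row evaluation
            expect = (design.X[r] @ b
                      + vs[design.row_state[r], design.row_disease[r]]
                      + vc[design.row_county[r], design.row_disease[r]])
            assert eta[r] == pytest.approx(expect, abs=1e-12)

    def test_dimension_mismatch_raises(self, small_instance):
        design, params, raneff, *_ = small_instance
        bad = gp.ParameterSet(b=params.b.iloc[:3], sigma_state=params.sigma_state,
                              sigma_county=params.sigma_county)
        with pytest.raises((SchemaError, KeyError)):
            gp.linear_predictor(design, bad, raneff)


class TestConditionalLoglik:
    def test_poisson_part_unit_mean_zero_count(self):
        """One row, N = 1, eta = 0, y = 0: log P = -1 exactly."""
        design, params = make_single_cell(0, 1, 1e-12, 1e-12, 0.0)
        eta = np.zeros(1)
        assert gmodel.poisson_loglik(design, eta) == pytest.approx(-1.0, abs=1e-12)

    def test_poisson_part_offset_form(self):
        """N = 1000, eta = log 0.001, y = 1: mean 1, log P = -1."""
        design, params = make_single_cell(1, 1000, 1e-12, 1e-12, np.log(0.001))
        eta = np.full(1, np.log(0.001))
        assert gmodel.poisson_loglik(design, eta) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, small_instance):
        """Independent reimplementation, summing terms in reverse row order
        with the normal densities expanded by hand, to 1e-12."""
        design, params, raneff, *_ = small_instance
        got = gp.conditional_loglik(design, params, raneff)

        b = design.b_vector(params)
        vs, vc = design.raneff_arrays(raneff)
        total = 0.0
        for r in reversed(range(design.n_rows)):
            eta = (design.X[r] @ b
                   + vs[design.row_state[r], design.row_disease[r]]
                   + vc[design.row_county[r], design.row_disease[r]])
            y, N = design.y[r], design.N[r]
            total += y * (np.log(N) + eta) - N * np.exp(eta) - gammaln(y + 1)
        for v, sig in ((vs, params.sigma_state), (vc, params.sigma_county)):
            inv = np.linalg.inv(sig)
            _, logdet = np.linalg.slogdet(sig)
            for row in v:
                total += -0.5 * row @ inv @ row \
                    - 0.5 * (2 * np.log(2 * np.pi) + logdet)
        assert got == pytest.approx(total, abs=1e-12 * max(1, abs(total)))

    def test_invariant_to_input_row_permutation(self, small_instance):
        design, params, raneff, panel, covars, geo, spec = small_instance
        shuffled = gp.IncidencePanel(
            panel.data.sample(frac=1.0, random_state=4).reset_index(drop=True))
        design2 = gp.build_design(shuffled, covars, geo, spec)
        a = gp.conditional_loglik(design, params, raneff)
        b = gp.conditional_loglik(design2, params, raneff)
        assert a == pytest.approx(b, rel=1e-14)

    def test_singular_covariance_rejected(self, small_instance):
        design, params, raneff, *_ = small_instance
        bad = gp.ParameterSet(b=params.b, sigma_state=np.zeros((2, 2)),
                              sigma_county=params.sigma_county)
        with pytest.raises(ValidationError):
            gp.conditional_loglik(design, bad, raneff)


class TestMarginalLoglik:
    def test_degenerate_limit_equals_fixed_effects_glm(self):
        """At variance 1e-10 on data with no latent heterogeneity, the
        marginal collapses onto the fixed-effects Poisson log-likelihood
        (the residual gap is ~ sigma^2 times the squared residual sums)."""
        geo = gp.generate_geography(
            3, 3, pop_distribution={"dist": "constant", "value": 100_000},
            seed=5)
        covars = gp.generate_covariates(geo, seed=5)
        spec = gp.ModelSpec(covariates={"ASD": ("Gender", "Income"),
                                        "ID": ("Gender", "Income")})
        b = pd.Series({"ASD:Intercept": -6.5, "ASD:Gender": -0.7,
                       "ASD:Income": 0.02, "ID:Intercept": -7.0,
                       "ID:Gender": -0.1, "ID:Income": 0.01})
        gen = gp.ParameterSet(b=b, sigma_state=np.zeros((2, 2)),
                              sigma_county=np.zeros((2, 2)))
        panel, _ = gp.simulate_panel(geo, covars, gen, spec, seed=6)
        design = gp.build_design(panel, covars, geo, spec)
        tiny = gp.ParameterSet(b=b, sigma_state=1e-10 * np.eye(2),
                               sigma_county=1e-10 * np.eye(2))
        glm = gmodel.poisson_loglik(design, design.X @ design.b_vector(tiny))
        for method in ("laplace", "adaptive_quadrature"):
            got = gp.marginal_loglik(design, tiny, method=method)
            assert got == pytest.approx(glm, abs=1e-6)

    def test_single_cell_against_trapezoid_oracle(self):
        """Single state/county/disease/row: both approximations agree with a
        fine-grid 1-D integration over the summed random effect."""
        y, N, v = 1_000_000, 1_000_000_000, 1e-4
        design, params = make_single_cell(y, N, v, v, np.log(y / N))
        oracle = trapezoid_marginal(np.log(y / N), 2 * v, y, N)
        lap = gp.marginal_loglik(design, params, method="laplace")
        agq = gp.marginal_loglik(design, params, method="adaptive_quadrature",
                                 n_quad=25)
        assert lap == pytest.approx(oracle, abs=1e-6)
        assert agq == pytest.approx(oracle, abs=1e-6)

    def test_single_cell_moderate_counts(self):
        """At moderate counts adaptive quadrature stays at 1e-6 while the
        Laplace approximation is only ~1e-4 accurate."""
        y, N, v = 100, 100_000, 0.02
        design, params = make_single_cell(y, N, v / 2, v / 2, np.log(y / N))
        oracle = trapezoid_marginal(np.log(y / N), v, y, N)
        agq = gp.marginal_loglik(design, params, method="adaptive_quadrature",
                                 n_quad=25)
        lap = gp.marginal_loglik(design, params, method="laplace")
        assert agq == pytest.approx(oracle, abs=1e-6)
        assert lap == pytest.approx(oracle, abs=5e-4)

    def test_empty_state_leaves_value_unchanged(self, small_instance):
        design, params, raneff, panel, covars, geo, spec = small_instance
        base = gp.marginal_loglik(design, params)
        geo2 = gp.GeoHierarchy(
            states=pd.concat([geo.states, pd.DataFrame(
                [{"state_id": "S99", "CFR": 1, "DSM": 1, "ASDcrit": 1,
                  "Eval": 1}])], ignore_index=True),
            counties=geo.counties)
        design2 = gp.build_design(panel, covars, geo2, spec)
        assert gp.marginal_loglik(design2, params) == pytest.approx(base, rel=1e-12)

    def test_methods_agree_on_desk_instance(self, small_instance):
        design, params, *_ = small_instance
        lap = gp.marginal_loglik(design, params, method="laplace")
        agq = gp.marginal_loglik(design, params, method="adaptive_quadrature",
                                 n_quad=15)
        assert lap == pytest.approx(agq, abs=1e-3)

    def test_offset_doubling_with_halved_rate_is_exact(self, small_instance):
        """Doubling every offset while subtracting log 2 from the intercepts
        leaves the likelihood's non-constant part unchanged; the conditional
        likelihood is invariant exactly."""
        design, params, raneff, panel, covars, geo, spec = small_instance
        doubled = panel.data.copy()
        doubled["N"] = doubled["N"] * 2
        design2 = gp.build_design(gp.IncidencePanel(doubled), covars, geo, spec)
        b2 = params.b.copy()
        b2["ASD:Intercept"] -= np.log(2)
        b2["ID:Intercept"] -= np.log(2)
        params2 = gp.ParameterSet(b=b2, sigma_state=params.sigma_state,
                                  sigma_county=params.sigma_county)
        a = gp.conditional_loglik(design, params, raneff)
        b = gp.conditional_loglik(design2, params2, raneff)
        assert a == pytest.approx(b, rel=1e-12)
        am = gp.marginal_loglik(design, params)
        bm = gp.marginal_loglik(design2, params2)
        assert am == pytest.approx(bm, rel=1e-9)

    def test_unknown_method_rejected(self, small_instance):
        design, params, *_ = small_instance
        with pytest.raises(ValueError):
            gp.marginal_loglik(design, params, method="saddlepoint")


class TestBlockDiagonality:
    def test_perturbing_one_disease_leaves_other_fitted_rates_unchanged(
            self, small_instance):
        design, params, raneff, *_ = small_instance
        zero_re = gp.RandomEffects(v_state=raneff.v_state * 0,
                                   v_county=raneff.v_county * 0)
        eta0 = gp.linear_predictor(design, params, zero_re)
        b2 = params.b.copy()
        b2["ASD:Income"] += 0.5
        bumped = gp.ParameterSet(b=b2, sigma_state=params.sigma_state,
                                 sigma_county=params.sigma_county)
        eta1 = gp.linear_predictor(design, bumped, zero_re)
        id_rows = design.row_disease == 1
        assert np.array_equal(eta0[id_rows], eta1[id_rows])
        assert not np.allclose(eta0[~id_rows], eta1[~id_rows])


class TestTransforms:
    @pytest.mark.parametrize("weight, rate", [
        (1.344962, 3.838041),   # male genital malformations, ASD submodel
        (0.0, 1.0),
        (-0.699367, 0.496900),  # gender covariate, ASD submodel
        (0.660186, 1.935152),   # male genital malformations, ID submodel
    ])
    def test_event_rate_ratio(self, weight, rate):
        assert gp.event_rate_ratio(weight) == pytest.approx(rate, abs=5e-7)

    @pytest.mark.parametrize("weight, pct", [
        (1.344962, 283.8041),
        (0.276762, 31.8852),
        (0.0, 0.0),
    ])
    def test_percent_change(self, weight, pct):
        assert gp.percent_change(weight) == pytest.approx(pct, abs=5e-3)

    @pytest.mark.parametrize("cov, v1, v2, r", [
        (2.666, 3.126, 2.398, 0.974),   # state level
        (0.6960, 0.7699, 0.6796, 0.962),  # county level
        (0.0, 1.0, 2.0, 0.0),
    ])
    def test_random_effect_correlation(self, cov, v1, v2, r):
        assert gp.random_effect_correlation(cov, v1, v2) == pytest.approx(
            r, abs=5e-4)

    def test_correlation_domain_errors(self):
        with pytest.raises(ValidationError):
            gp.random_effect_correlation(0.5, -1.0, 1.0)
        with pytest.raises(ValidationError):
            gp.random_effect_correlation(2.0, 1.0, 1.0)

    def test_non_finite_weight_rejected(self):
        with pytest.raises(ValidationError):
            gp.event_rate_ratio(np.inf)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=-99.0, max_value=1e4,
                     allow_nan=False, allow_infinity=False))
    def test_percent_change_log_round_trip(self, p):
        back = gp.percent_change(np.log(1 + p / 100.0))
        assert back == pytest.approx(p, rel=1e-9, abs=1e-9)
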