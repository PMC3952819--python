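"""Shared fixtures: all test data is generated programmatically."""

import warnings

import numpy as np
import pandas as pd
import pytest

import geopoisson as gp
from geopoisson.types import COVARIATE_COLUMNS


@pytest.fixture(scope="session")
def paper_scale():
    """51 states x 3,111 counties: geography, covariates, panel, design."""
    geo = gp.generate_geography(n_states=51, counties_per_state=61, seed=1)
    covars = gp.generate_covariates(geo, seed=1)
    panel, raneff = gp.simulate_panel(geo, covars, seed=1)
    design = gp.build_design(panel, covars, geo, gp.ModelSpec())
    return {"geo": geo, "covars": covars, "panel": panel,
            "raneff": raneff, "design": design}


@pytest.fixture(scope="session")
def desk_fit_instance():
    """Moderate-count mixed-model dataset with known truth (6 states x 15
    counties, 4 covariates per disease) shared by the Laplace fit tests."""
    geo = gp.generate_geography(
        6, 15, pop_distribution={"dist": "constant", "value": 400_000}, seed=17)
    covars = gp.generate_covariates(geo, seed=17)
    spec = gp.ModelSpec(covariates={
        "ASD": ("Gender", "Income", "Urban", "ConGenM"),
        "ID": ("Gender", "Income", "Urban", "ConGenM"),
    })
    truth = gp.ParameterSet(
        b=pd.Series({
            "ASD:Intercept": -6.9, "ASD:Gender": -0.699367,
            "ASD:Income": 0.032, "ASD:Urban": 0.036, "ASD:ConGenM": 1.345,
            "ID:Intercept": -7.4, "ID:Gender": -0.114,
            "ID:Income": 0.027, "ID:Urban": 0.031, "ID:ConGenM": 0.66,
        }),
        sigma_state=[[0.5, 0.4], [0.4, 0.5]],
        sigma_county=[[0.4, 0.3], [0.3, 0.4]],
    )
    panel, raneff = gp.simulate_panel(geo, covars, truth, spec, seed=18)
    design = gp.build_design(panel, covars, geo, spec)
    return {"geo": geo, "covars": covars, "spec": spec, "truth": truth,
            "panel": panel, "raneff": raneff, "design": design}


def make_single_cell(y, N, var_state, var_county, intercept):
    """One state, one county, one disease, one observed row.

    The female row has zero population, so the design reduces to a single
    Poisson cell with one state and one county random effect.
    """
    geo = gp.GeoHierarchy(
        states=pd.DataFrame({"state_id": ["S01"], "CFR": [1], "DSM": [1],
                             "ASDcrit": [1], "Eval": [1]}),
        counties=pd.DataFrame({"county_id": ["S01C1"], "state_id": ["S01"],
                               "pop_male": [N], "pop_female": [0]}),
    )
    covrow = {c: 1.0 for c in COVARIATE_COLUMNS}
    covars = gp.CovariateTable(pd.DataFrame([{"county_id": "S01C1", **covrow}]))
    panel = gp.IncidencePanel(pd.DataFrame(
        [{"county_id": "S01C1", "disease": "ASD", "gender": "M", "y": y, "N": N},
         {"county_id": "S01C1", "disease": "ASD", "gender": "F", "y": 0, "N": 0}]))
    spec = gp.ModelSpec(diseases=("ASD",), covariates={"ASD": ("Gender",)},
                        center=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = gp.build_design(panel, covars, geo, spec)
    params = gp.ParameterSet(
        b=pd.Series({"ASD:Intercept": intercept, "ASD:Gender": 0.0}),
        sigma_state=[[var_state]], sigma_county=[[var_county]],
    )
    return design, params


def trapezoid_marginal(intercept, total_var, y, N, ngrid=400_001, span=16.0):
    """Fine-grid trapezoid oracle for the single-cell marginal likelihood.

    The state and county effects enter only through their sum, so the exact
    marginal is a one-dimensional integral over w ~ N(0, total_var).
    """
    from scipy.special import gammaln, logsumexp
    w = np.linspace(-span * np.sqrt(total_var), span * np.sqrt(total_var), ngrid)
    eta = intercept + w
    logf = (y * (np.log(N) + eta) - N * np.exp(eta) - gammaln(y + 1)
            - 0.5 * w ** 2 / total_var - 0.5 * np.log(2 * np.pi * total_var))
    return float(logsumexp(logf) + np.log(w[1] - w[0]))
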