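"""Synthetic county-level epidemiologic data with the model's exact structure.

The real analysis runs on proprietary claims-derived county tables; this
module generates stand-in data with the same statistical skeleton — a
state -> county hierarchy with gender-stratified populations, per-county
covariates (ethnic composition, socioeconomics, population-normalised
malformation and infection rates), hand-coded-style state policy variables,
bivariate-normal random effects correlated across the two phenotypes at
both levels, and Poisson incidence counts with population offsets.

Defaults are calibrated so the descriptive layer of the synthetic data
matches the published county-level summaries (ASD male county rates with
mean ~0.1% and a skewed distribution, genital-malformation rates averaging
~0.27% with county maxima around 2.4%), and the default "true" regression
weights and covariance matrices are the published point estimates, so
parameter-recovery experiments run at realistic magnitudes.  The covariate
distributions themselves are fixtures: the source data's distributions were
never published.

All generators are bit-reproducible for a fixed seed, with one RNG stream
per stage.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from . import model as _model
from .types import (
    COVARIATE_COLUMNS,
    ETHNIC_COLUMNS,
    POLICY_COLUMNS,
    CovariateTable,
    GeoHierarchy,
    IncidencePanel,
    ModelSpec,
    ParameterSet,
    PatientTable,
    RandomEffects,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "generate_geography",
    "generate_covariates",
    "simulate_panel",
    "generate_patients",
    "default_parameters",
    "DEFAULT_POP_DISTRIBUTION",
    "DEFAULT_COVARIATE_CONFIG",
    "DEFAULT_POLICY_FREQUENCIES",
    "PAPER_SCALE",
    "DESK_SCALE",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class FeasibilityError(ValueError):
    """Requested joint distribution is unattainable given the marginals."""


#: County gender-specific populations: log-normal, heavy right tail like US
#: county sizes.  median/sigma on the natural scale (persons per gender).
DEFAULT_POP_DISTRIBUTION: dict = {"dist": "lognormal", "median": 10_000.0, "sigma": 1.3}

#: i.i.d. per-state frequencies for the four policy codes.
DEFAULT_POLICY_FREQUENCIES: dict = {
    "CFR": {-1: 0.5, 1: 0.5},
    "DSM": {-1: 0.5, 1: 0.5},
    "ASDcrit": {-1: 0.5, 1: 0.5},
    "Eval": {-2: 0.2, -1: 0.2, 1: 0.3, 2: 0.3},
}

#: Per-covariate marginal distributions.  Percent covariates are truncated
#: to [0, 100] by rejection; ethnic proportions are drawn jointly from a
#: scaled Dirichlet with a remainder category so their sum stays <= 100.
#: The malformation/viral gamma shapes are right-skewed so county maxima
#: reach the published extremes (e.g. ConGenM mean ~0.27%, max ~2.4%).
DEFAULT_COVARIATE_CONFIG: dict = {
    "Income": {"dist": "lognormal", "median": 43.0, "sigma": 0.25},  # $1000s
    "Poor": {"dist": "beta", "a": 2.5, "b": 14.0, "scale": 100.0},
    "Urban": {"dist": "beta", "a": 1.6, "b": 1.1, "scale": 100.0},
    "Insured": {"dist": "beta", "a": 14.0, "b": 3.0, "scale": 100.0},
    "ethnic": {
        # AmInd, Asian, WHisp, W, BHisp, B, Pacific + implicit remainder;
        # concentration keeps county-to-county dispersion near census-like
        # levels (W sd ~6%, small groups sd ~1-2%)
        "alpha": [0.9, 1.5, 6.0, 36.0, 0.9, 4.5, 0.3, 3.9],
        "scale": 100.0,
    },
    "ConGenM": {"dist": "gamma", "shape": 0.8, "scale": 0.33},
    "ConGenF": {"dist": "gamma", "shape": 0.8, "scale": 0.25},
    "CongMrepM": {"dist": "gamma", "shape": 3.0, "scale": 0.4},
    "CongMrepF": {"dist": "gamma", "shape": 3.0, "scale": 0.36},
    "Viral_M": {"dist": "gamma", "shape": 3.0, "scale": 0.65},
    "Viral_F": {"dist": "gamma", "shape": 3.0, "scale": 0.6},
    "ect_pr": {"dist": "gamma", "shape": 1.2, "scale": 0.25},
    "abnormal_concept": {"dist": "gamma", "shape": 1.2, "scale": 0.3},
    "spont_abort": {"dist": "gamma", "shape": 1.5, "scale": 0.5},
    "mult_gest": {"dist": "gamma", "shape": 1.5, "scale": 0.4},
}

#: Scale presets: the published study geometry vs a quick desk-size run.
PAPER_SCALE = {"n_states": 51, "counties_per_state": 61}   # 3,111 counties
DESK_SCALE = {"n_states": 10, "counties_per_state": 20}    # 200 counties

#: Default "true" fixed-effect weights for the simulator, at published
#: magnitudes.  Intercepts are set so county rates land on the published
#: descriptive scale (ASD male rates: median ~0.023%, mean ~0.1%) once the
#: random-effect variances below are added on the log scale.
_TRUE_B_ASD = {
    "Intercept": -8.40, "Gender": -0.699367, "Income": 0.032462,
    "Poor": -0.035009, "Urban": 0.036144, "Insured": -0.012102,
    "AmInd": -0.131310, "Asian": -0.045453, "WHisp": -0.127715,
    "W": -0.121627, "BHisp": 0.085030, "B": -0.130750, "Pacific": -0.438859,
    "ConGenM": 1.344962, "CongMrepM": 0.276762, "Viral_M": 0.180043,
    "CFR": -0.099843, "DSM": 0.138073, "ASDcrit": -0.175057,
    "Eval1": -4.231486, "Eval2": -0.213462, "Eval-1": 0.667525,
}
_TRUE_B_ID = {
    "Intercept": -9.90, "Gender": -0.114004, "Income": 0.027171,
    "Poor": -0.013068, "Urban": 0.031155, "Insured": 0.004845,
    "AmInd": -0.138735, "Asian": -0.065537, "WHisp": -0.130204,
    "W": -0.126588, "BHisp": 0.032889, "B": -0.130235, "Pacific": -0.373752,
    "ConGenM": 0.660186, "CongMrepM": 0.362239, "Viral_M": 0.211402,
    "CFR": 0.102626, "DSM": 0.149366, "ASDcrit": -0.109237,
    "Eval1": -4.535572, "Eval2": -0.063085, "Eval-1": 0.417890,
}
_TRUE_B = {"ASD": _TRUE_B_ASD, "ID": _TRUE_B_ID}

#: Default random-effect covariances across the two phenotypes (published
#: point estimates; state-level correlation 0.974, county-level 0.962).
DEFAULT_SIGMA_STATE = np.array([[3.126, 2.666], [2.666, 2.398]])
DEFAULT_SIGMA_COUNTY = np.array([[0.7699, 0.6960], [0.6960, 0.6796]])


def default_parameters(spec: ModelSpec | None = None) -> ParameterSet:
    """The simulator's default true parameters, aligned to a model spec."""
    spec = spec or ModelSpec()
    vals = {}
    for dis in spec.diseases:
        table = _TRUE_B.get(dis, {})
        vals[f"{dis}:Intercept"] = table.get("Intercept", -8.5)
        for name in spec.covariates[dis]:
            vals[f"{dis}:{name}"] = table.get(name, 0.0)
    d = spec.n_diseases
    return ParameterSet(
        b=pd.Series(vals),
        sigma_state=DEFAULT_SIGMA_STATE[:d, :d].copy(),
        sigma_county=DEFAULT_SIGMA_COUNTY[:d, :d].copy(),
    )


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def generate_geography(
    n_states: int,
    counties_per_state: int | tuple[int, int],
    pop_distribution: Mapping | None = None,
    seed: int = 0,
    policy_frequencies: Mapping | None = None,
) -> GeoHierarchy:
    """Generate a state -> county hierarchy with gender populations.

    ``counties_per_state`` is either a fixed count or an inclusive
    ``(low, high)`` range drawn uniformly per state.  Gender populations are
    drawn independently per county from ``pop_distribution`` (log-normal by
    default).  State policy codes are assigned i.i.d. from
    ``policy_frequencies``.  Deterministic for fixed seed.
    """
    if n_states < 1:
        raise ConfigurationError("n_states must be >= 1")
    pop_cfg = dict(DEFAULT_POP_DISTRIBUTION, **(pop_distribution or {}))
    if pop_cfg.get("median", 1) <= 0:
        raise ConfigurationError("population median must be positive")
    freqs = policy_frequencies or DEFAULT_POLICY_FREQUENCIES
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(0,)))

    if isinstance(counties_per_state, (tuple, list)):
        lo, hi = counties_per_state
        if lo < 1 or hi < lo:
            raise ConfigurationError("invalid counties_per_state range")
        per_state = rng.integers(lo, hi + 1, size=n_states)
    else:
        if counties_per_state < 1:
            raise ConfigurationError("counties_per_state must be >= 1")
        per_state = np.full(n_states, int(counties_per_state))

    width = max(2, len(str(n_states)))
    state_ids = [f"S{i + 1:0{width}d}" for i in range(n_states)]

    policy = {}
    for col in POLICY_COLUMNS:
        f = freqs[col]
        levels = np.array(sorted(f))
        probs = np.array([f[lv] for lv in levels], dtype=float)
        probs = probs / probs.sum()
        policy[col] = levels[rng.choice(len(levels), size=n_states, p=probs)]
    states = pd.DataFrame({"state_id": state_ids, **policy})

    rows = []
    for i, sid in enumerate(state_ids):
        for j in range(per_state[i]):
            rows.append((f"{sid}C{j + 1:04d}", sid))
    counties = pd.DataFrame(rows, columns=["county_id", "state_id"])
    n_c = len(counties)
    if pop_cfg["dist"] == "lognormal":
        mu = np.log(pop_cfg["median"])
        pops = rng.lognormal(mu, pop_cfg["sigma"], size=(n_c, 2))
    elif pop_cfg["dist"] == "constant":
        pops = np.full((n_c, 2), float(pop_cfg["value"]))
    else:
        raise ConfigurationError(f"unknown population distribution {pop_cfg['dist']!r}")
    counties["pop_male"] = np.round(pops[:, 0]).astype(np.int64)
    counties["pop_female"] = np.round(pops[:, 1]).astype(np.int64)
    return GeoHierarchy(states=states, counties=counties)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _draw_marginal(rng: np.random.Generator, cfg: Mapping, n: int,
                   lo: float, hi: float, name: str) -> np.ndarray:
    """Draw n values, rejecting-and-resampling anything outside [lo, hi]."""
    def draw(size):
        dist = cfg["dist"]
        if dist == "gamma":
            return rng.gamma(cfg["shape"], cfg["scale"], size)
        if dist == "lognormal":
            return rng.lognormal(np.log(cfg["median"]), cfg["sigma"], size)
        if dist == "beta":
            return cfg.get("scale", 1.0) * rng.beta(cfg["a"], cfg["b"], size)
        if dist == "normal":
            return rng.normal(cfg["mean"], cfg["sd"], size)
        if dist == "constant":
            return np.full(size, float(cfg["value"]))
        raise ConfigurationError(f"unknown distribution {dist!r} for {name}")

    vals = draw(n)
    bad = (vals < lo) | (vals > hi)
    n_resampled = 0
    while bad.any():
        if cfg["dist"] == "constant":
            raise ConfigurationError(f"constant value for {name} outside [{lo}, {hi}]")
        vals[bad] = draw(int(bad.sum()))
        n_resampled += int(bad.sum())
        bad = (vals < lo) | (vals > hi)
    if n_resampled:
        logger.info("covariate %s: resampled %d out-of-range draws", name, n_resampled)
    return vals


def generate_covariates(
    geo: GeoHierarchy,
    config: Mapping | None = None,
    seed: int = 0,
) -> CovariateTable:
    """Generate the per-county covariate table.

    Ethnic proportions are drawn jointly (scaled Dirichlet with a remainder
    category) so their sum never exceeds 100; every other covariate is drawn
    from its configured marginal, with out-of-range draws rejected and
    resampled.  Policy codes stay as assigned on the geography unless the
    config carries a ``"policy"`` entry, in which case they are reassigned
    per state from those frequencies.
    """
    cfg = dict(DEFAULT_COVARIATE_CONFIG)
    if config:
        for k, v in config.items():
            cfg[k] = v
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))
    n = geo.n_counties
    out = pd.DataFrame({"county_id": geo.counties["county_id"].to_numpy()})

    alpha = np.asarray(cfg["ethnic"]["alpha"], dtype=float)
    if len(alpha) != len(ETHNIC_COLUMNS) + 1:
        raise ConfigurationError(
            "ethnic alpha must have one entry per ethnic column plus a remainder")
    props = rng.dirichlet(alpha, size=n) * cfg["ethnic"].get("scale", 100.0)
    for j, col in enumerate(ETHNIC_COLUMNS):
        out[col] = props[:, j]

    for col in COVARIATE_COLUMNS:
        if col in ETHNIC_COLUMNS:
            continue
        lo, hi = (0.0, np.inf) if col == "Income" else (0.0, 100.0)
        out[col] = _draw_marginal(rng, cfg[col], n, lo, hi, col)

    if config and "policy" in config:
        freqs = config["policy"]
        for col in POLICY_COLUMNS:
            f = freqs[col]
            levels = np.array(sorted(f))
            probs = np.array([f[lv] for lv in levels], dtype=float)
            probs /= probs.sum()
            geo.states[col] = levels[rng.choice(len(levels), size=geo.n_states, p=probs)]

    return CovariateTable(data=out)


# ---------------------------------------------------------------------------
# incidence panel
# ---------------------------------------------------------------------------

def _mvn_factor(sigma: np.ndarray) -> np.ndarray:
    """Factor A with A A' = sigma, valid for singular PSD matrices."""
    w, V = np.linalg.eigh(np.asarray(sigma, float))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_panel(
    geo: GeoHierarchy,
    covars: CovariateTable,
    params: ParameterSet | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
    max_rate: float = 0.5,
) -> tuple[IncidencePanel, RandomEffects]:
    """Draw Poisson incidence counts under the model; return the truth.

    State and county effects are drawn from the bivariate normals defined by
    ``params``; the linear predictor is evaluated through the same design
    construction the fitters use; counts are Poisson with mean
    ``N * exp(eta)``.  Random-effect configurations implying a cell
    incidence rate above ``max_rate`` — far beyond anything a claims panel
    exhibits — are rejected and redrawn (the truncation region is a remote
    Gaussian tail under the defaults; the redraw count is logged).  Counts
    are finally clipped at N so the panel invariant y <= N always holds.
    Returns the panel and the realised random effects for recovery testing.
    Zero-population cells always yield y = 0.
    """
    spec = spec or ModelSpec()
    params = params if params is not None else default_parameters(spec)
    if params.n_diseases != spec.n_diseases:
        raise ValidationError("params dimension does not match spec diseases")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2,)))

    counties = geo.counties.sort_values(["state_id", "county_id"], kind="stable")
    genders = [spec.gender_reference] + [g for g in ("M", "F")
                                         if g != spec.gender_reference]
    pop_col = {"M": "pop_male", "F": "pop_female"}
    rows = []
    for _, c in counties.iterrows():
        for dis in spec.diseases:
            for g in genders:
                rows.append((c["county_id"], dis, g, 0, int(c[pop_col[g]])))
    panel_df = pd.DataFrame(rows, columns=["county_id", "disease", "gender", "y", "N"])

    d = spec.n_diseases
    As = _mvn_factor(params.sigma_state)
    Ac = _mvn_factor(params.sigma_county)
    state_ids = geo.states.sort_values("state_id", kind="stable")["state_id"].to_numpy()
    design = _model.build_design(IncidencePanel(panel_df), covars, geo, spec)
    for attempt in range(1000):
        vs = rng.standard_normal((len(state_ids), d)) @ As.T
        vc = rng.standard_normal((len(counties), d)) @ Ac.T
        raneff = RandomEffects(
            v_state=pd.DataFrame(vs, index=list(state_ids),
                                 columns=list(spec.diseases)),
            v_county=pd.DataFrame(vc, index=list(counties["county_id"]),
                                  columns=list(spec.diseases)),
        )
        eta = _model.linear_predictor(design, params, raneff)
        if np.exp(eta).max() <= max_rate:
            break
    else:
        raise ValidationError(
            f"could not draw random effects keeping all rates below {max_rate}; "
            "parameters imply routinely impossible incidence")
    if attempt:
        logger.info("simulate_panel: redrew random effects %d time(s) to keep "
                    "rates below %.2f", attempt, max_rate)
    y = rng.poisson(design.N * np.exp(eta))
    y = np.minimum(y, design.N.astype(np.int64))

    # map design rows (zero-offset rows were dropped) back onto the panel
    key = pd.MultiIndex.from_arrays([
        design.county_ids[design.row_county],
        [spec.diseases[k] for k in design.row_disease],
        [genders[g] for g in design.row_gender],
    ])
    y_map = pd.Series(y, index=key)
    panel_key = pd.MultiIndex.from_frame(panel_df[["county_id", "disease", "gender"]])
    panel_df["y"] = y_map.reindex(panel_key).fillna(0).to_numpy(np.int64)
    return IncidencePanel(panel_df), raneff


# ---------------------------------------------------------------------------
# patient-level comorbidity table
# ---------------------------------------------------------------------------

def joint_from_or(p_row: float, p_col: float, odds_ratio: float) -> np.ndarray:
    """2x2 cell probabilities with given margins and odds ratio.

    Solves the Plackett quadratic for p11; degenerate margins (0 or 1)
    return the independence table (the odds ratio is then undefined, so any
    target is vacuously met).
    """
    if not np.isfinite(odds_ratio) or odds_ratio <= 0:
        raise FeasibilityError(
            f"odds ratio {odds_ratio} unattainable; attainable range is (0, inf)")
    if p_row in (0.0, 1.0) or p_col in (0.0, 1.0) or odds_ratio == 1.0:
        p11 = p_row * p_col
    else:
        s = 1.0 + (p_row + p_col) * (odds_ratio - 1.0)
        disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_row * p_col
        p11 = (s - np.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    p10 = p_row - p11
    p01 = p_col - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([p11, p10, p01, p00])
    if (probs < -1e-12).any():
        raise FeasibilityError(
            f"margins ({p_row}, {p_col}) infeasible for odds ratio {odds_ratio}")
    return np.clip(probs, 0.0, 1.0)


def generate_patients(
    panel: IncidencePanel,
    covars: CovariateTable,
    target_or: float,
    seed: int = 0,
    target_or_id: float = 1.0,
    sampling_fraction: float = 1.0,
) -> PatientTable:
    """Patient-level flags whose (ASD, ConGen) joint hits a target odds ratio.

    Within each (county, gender) stratum the marginal flag probabilities are
    the panel's observed disease rates and the covariate table's
    malformation rates; the joint distribution of (flag_ASD, flag_ConGen)
    is the 2x2 table with those margins and odds ratio ``target_or``
    (``target_or_id`` likewise couples flag_ID to flag_ConGen,
    independently of flag_ASD given the margins).  ``sampling_fraction``
    subsamples each stratum's population.
    """
    if target_or <= 0:
        raise FeasibilityError("target_or must be positive; attainable range (0, inf)")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(3,)))
    df = panel.data
    cov = covars.data.set_index("county_id")
    gender_col = {"M": "ConGenM", "F": "ConGenF"}

    parts = []
    for (county, gender), grp in df.groupby(["county_id", "gender"], sort=True):
        n_pop = int(grp["N"].iloc[0])
        n = int(round(n_pop * sampling_fraction))
        if n == 0:
            continue
        rate = dict(zip(grp["disease"], grp["y"] / grp["N"].clip(lower=1)))
        p_asd = float(rate.get("ASD", 0.0))
        p_id = float(rate.get("ID", 0.0))
        p_cg = float(cov.loc[county, gender_col[gender]]) / 100.0

        cells = joint_from_or(p_asd, p_cg, target_or)
        n11, n10, n01, n00 = rng.multinomial(n, cells)
        # ID flag: joint with ConGen at target_or_id, independent of ASD
        cells_id = joint_from_or(p_id, p_cg, target_or_id)
        p_id_given_cg = cells_id[0] / p_cg if p_cg > 0 else 0.0
        p_id_given_ncg = cells_id[1] / (1 - p_cg) if p_cg < 1 else 0.0

        flag_asd = np.repeat([True, True, False, False], [n11, n10, n01, n00])
        flag_cg = np.repeat([True, False, True, False], [n11, n10, n01, n00])
        p_flag_id = np.where(flag_cg, p_id_given_cg, p_id_given_ncg)
        flag_id = rng.random(n) < p_flag_id
        parts.append(pd.DataFrame({
            "county_id": county, "gender": gender,
            "flag_ASD": flag_asd, "flag_ID": flag_id, "flag_ConGen": flag_cg,
        }))

    if parts:
        out = pd.concat(parts, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["county_id", "gender", "flag_ASD",
                                    "flag_ID", "flag_ConGen"])
    out.insert(0, "patient_id",
               np.char.add("P", np.arange(1, len(out) + 1).astype(str)))
    return PatientTable(data=out)
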