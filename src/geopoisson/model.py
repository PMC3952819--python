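"""Bivariate three-level mixed-effects Poisson model.

The observed count for county *ij* (nested in state *i*), disease *k* and
gender *l* is modelled as

    y_ijkl ~ Poisson(N_ijkl * lambda_ijkl),
    log lambda_ijkl = x_ijkl' b_k + v_ik + v_ijk,

with N the gender-specific county population offset, b_k the disease-
specific fixed-effect weights, and zero-mean random effects that are
independent across levels but correlated across the two diseases within a
level:

    (v_i1, v_i2)  ~ N(0, Sigma_state),   (v_ij1, v_ij2) ~ N(0, Sigma_county).

This module builds the centered block-diagonal design, evaluates the exact
conditional log-likelihood, and approximates the marginal log-likelihood
(random effects integrated out) by a per-state joint Laplace approximation
or by nested adaptive Gauss-Hermite quadrature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import gammaln, logsumexp

from .types import (
    _EVAL_INDICATORS,
    DesignBundle,
    GeoHierarchy,
    CovariateTable,
    IncidencePanel,
    ModelSpec,
    ParameterSet,
    RandomEffects,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "build_design",
    "linear_predictor",
    "poisson_loglik",
    "conditional_loglik",
    "marginal_loglik",
    "event_rate_ratio",
    "percent_change",
    "random_effect_correlation",
]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    panel: IncidencePanel,
    covars: CovariateTable,
    geo: GeoHierarchy,
    spec: ModelSpec | None = None,
) -> DesignBundle:
    """Assemble the centered block-diagonal fixed-effect design.

    Rows are ordered county-major (counties sorted by state then county id),
    and within each county by disease (spec order) then gender (reference
    gender first).  Each disease owns its own column block, so the two
    phenotypes have separate weights for every covariate.  Rows with a zero
    population offset are dropped with a warning.
    """
    spec = spec or ModelSpec()

    counties = geo.counties.sort_values(["state_id", "county_id"], kind="stable")
    county_ids = counties["county_id"].to_numpy()
    state_ids = geo.states.sort_values("state_id", kind="stable")["state_id"].to_numpy()
    state_pos = {s: i for i, s in enumerate(state_ids)}
    county_pos = {c: i for i, c in enumerate(county_ids)}
    county_state = np.array([state_pos[s] for s in counties["state_id"]], dtype=np.int64)

    missing = set(panel.data["county_id"]) - set(county_ids)
    if missing:
        raise SchemaError(f"panel counties absent from geography: {sorted(missing)[:5]}")
    cov = covars.data.set_index("county_id")
    missing = set(county_ids) - set(cov.index)
    if missing:
        raise SchemaError(f"counties missing covariates: {sorted(missing)[:5]}")
    cov = cov.loc[county_ids]
    policy = geo.states.set_index("state_id").loc[state_ids]

    # canonical row order via an explicit key frame
    genders = [spec.gender_reference] + sorted(
        set(panel.data["gender"]) - {spec.gender_reference}
    )
    key = panel.data.copy()
    key["_c"] = key["county_id"].map(county_pos)
    key["_k"] = key["disease"].map({d: i for i, d in enumerate(spec.diseases)})
    if key["_k"].isna().any():
        bad = sorted(set(key.loc[key["_k"].isna(), "disease"]))
        raise SchemaError(f"panel diseases not in model spec: {bad}")
    key["_l"] = key["gender"].map({g: i for i, g in enumerate(genders)})
    key = key.sort_values(["_c", "_k", "_l"], kind="stable")

    n0 = len(key)
    keep = key["N"].to_numpy() > 0
    if not keep.all():
        n_drop = int((~keep).sum())
        warnings.warn(f"dropping {n_drop} zero-offset row(s) from design", stacklevel=2)
        logger.warning("build_design: dropped %d zero-offset rows of %d", n_drop, n0)
        key = key.loc[keep]

    row_county = key["_c"].to_numpy(np.int64)
    row_state = county_state[row_county]
    row_disease = key["_k"].to_numpy(np.int64)
    row_gender = key["_l"].to_numpy(np.int64).clip(max=1)
    y = key["y"].to_numpy(np.int64)
    N = key["N"].to_numpy(float)

    # per-county covariate values resolved per row
    def column_values(name: str) -> np.ndarray:
        if name == "Gender":
            return row_gender.astype(float)
        if name in _EVAL_INDICATORS:
            lev = _EVAL_INDICATORS[name]
            if lev == spec.eval_reference:
                raise SchemaError(
                    f"covariate {name} is the Eval reference level; drop it from the spec"
                )
            ev = policy["Eval"].to_numpy()[row_state]
            return (ev == lev).astype(float)
        if name in ("CFR", "DSM", "ASDcrit"):
            return policy[name].to_numpy(float)[row_state]
        if name in cov.columns:
            return cov[name].to_numpy(float)[row_county]
        raise SchemaError(f"covariate {name!r} not found in covariates/policy tables")

    labels = spec.column_labels()
    p = len(labels)
    X = np.zeros((len(key), p), dtype=float)
    col_disease = np.empty(p, dtype=np.int64)
    col_means = np.zeros(p, dtype=float)
    j = 0
    for k, d in enumerate(spec.diseases):
        rows_k = row_disease == k
        X[rows_k, j] = 1.0  # intercept, never centered
        col_disease[j] = k
        j += 1
        for name in spec.covariates[d]:
            vals = column_values(name)
            if spec.center:
                m = vals[rows_k].mean()
                col_means[j] = m
                X[rows_k, j] = vals[rows_k] - m
            else:
                X[rows_k, j] = vals[rows_k]
            col_disease[j] = k
            j += 1

    return DesignBundle(
        y=y, N=N, X=X, col_labels=labels, col_disease=col_disease,
        row_state=row_state, row_county=row_county, row_disease=row_disease,
        row_gender=row_gender, state_ids=state_ids, county_ids=county_ids,
        county_state=county_state, spec=spec, col_means=col_means,
    )


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def linear_predictor(
    design: DesignBundle, params: ParameterSet, raneff: RandomEffects
) -> np.ndarray:
    """eta_row = (X b)_row + v_state(i, k) + v_county(ij, k).

    The expected count for a row is ``N * exp(eta)``.
    """
    design.subset_params(params)
    b = design.b_vector(params)
    vs, vc = design.raneff_arrays(raneff)
    return (
        design.X @ b
        + vs[design.row_state, design.row_disease]
        + vc[design.row_county, design.row_disease]
    )


def poisson_loglik(design: DesignBundle, eta: np.ndarray) -> float:
    """Sum over rows of ``y (log N + eta) - N exp(eta) - log(y!)``."""
    y, N = design.y, design.N
    return float(np.sum(y * (np.log(N) + eta) - N * np.exp(eta) - gammaln(y + 1.0)))


def _mvn_logpdf_rows(v: np.ndarray, sigma: np.ndarray) -> float:
    """Sum of N(0, sigma) log-densities over the rows of v."""
    d = sigma.shape[0]
    L = np.linalg.cholesky(sigma)
    z = np.linalg.solve(L, v.T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(
        -0.5 * np.sum(z * z) - 0.5 * v.shape[0] * (d * np.log(2 * np.pi) + logdet)
    )


def conditional_loglik(
    design: DesignBundle,
    params: ParameterSet,
    raneff: RandomEffects,
    include_random_effect_density: bool = True,
) -> float:
    """Exact joint log-likelihood at given random effects.

    The Poisson term sums ``y (log N + eta) - N exp(eta) - log(y!)`` over all
    rows; with ``include_random_effect_density`` the zero-mean bivariate
    normal log-densities of the state and county effects are added, giving
    the complete-data log-likelihood log p(y, v | theta).
    """
    for name, sig in (("sigma_state", params.sigma_state),
                      ("sigma_county", params.sigma_county)):
        if np.linalg.eigvalsh(sig).min() <= 0 and include_random_effect_density:
            raise ValidationError(f"{name} must be positive definite for the density term")
    eta = linear_predictor(design, params, raneff)
    out = poisson_loglik(design, eta)
    if include_random_effect_density:
        vs, vc = design.raneff_arrays(raneff)
        out += _mvn_logpdf_rows(vs, params.sigma_state)
        out += _mvn_logpdf_rows(vc, params.sigma_county)
    return out


# ---------------------------------------------------------------------------
# per-state blocks and marginal likelihood
# ---------------------------------------------------------------------------

@dataclass
class _StateBlock:
    """Rows and county bookkeeping for one state's random-effect block."""

    counties: np.ndarray      # county indices (global) in this state
    rows: np.ndarray          # row indices (global)
    xb: np.ndarray            # fixed-effect part of eta for these rows
    y: np.ndarray
    N: np.ndarray
    row_local_county: np.ndarray  # 0..m-1 within-state county of each row
    row_disease: np.ndarray


def _state_blocks(design: DesignBundle, b: np.ndarray) -> list[_StateBlock]:
    xb_all = design.X @ b
    blocks = []
    for i in range(design.n_states):
        counties = np.flatnonzero(design.county_state == i)
        rows = np.flatnonzero(design.row_state == i)
        local = {c: j for j, c in enumerate(counties)}
        row_local = np.array([local[c] for c in design.row_county[rows]], dtype=np.int64)
        blocks.append(
            _StateBlock(
                counties=counties, rows=rows, xb=xb_all[rows],
                y=design.y[rows].astype(float), N=design.N[rows],
                row_local_county=row_local, row_disease=design.row_disease[rows],
            )
        )
    return blocks


def _block_objective(blk: _StateBlock, u: np.ndarray, d: int,
                     prec_s: np.ndarray, prec_c: np.ndarray,
                     logdet_s: float, logdet_c: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-integrand f(u), gradient and (negative-definite) Hessian.

    ``u`` stacks the state effect (d entries) then the m county effects
    (d entries each).  f(u) = Poisson log-lik of the block's rows at
    eta = xb + v_state[k] + v_county[c, k], plus the normal log-priors.
    """
    m = len(blk.counties)
    vs = u[:d]
    vc = u[d:].reshape(m, d)
    eta = blk.xb + vs[blk.row_disease] + vc[blk.row_local_county, blk.row_disease]
    mu = blk.N * np.exp(eta)
    f = float(np.sum(blk.y * eta - mu))  # constants handled by caller
    resid = blk.y - mu

    g = np.zeros_like(u)
    # state-effect gradient: sum residuals by disease
    np.add.at(g, blk.row_disease, resid)
    # county-effect gradients
    np.add.at(g, d + blk.row_local_county * d + blk.row_disease, resid)

    # Hessian of the Poisson part: -mu accumulated into the coupled entries
    n_u = d + m * d
    H = np.zeros((n_u, n_u))
    w_state = np.zeros(d)
    np.add.at(w_state, blk.row_disease, mu)
    H[:d, :d] -= np.diag(w_state)
    w_cty = np.zeros((m, d))
    np.add.at(w_cty, (blk.row_local_county, blk.row_disease), mu)
    for k in range(d):
        idx = d + np.arange(m) * d + k
        H[idx, idx] -= w_cty[:, k]
        H[k, idx] -= w_cty[:, k]
        H[idx, k] -= w_cty[:, k]

    # priors
    f += -0.5 * vs @ prec_s @ vs - 0.5 * (d * np.log(2 * np.pi) + logdet_s)
    f += -0.5 * np.einsum("ij,jk,ik->", vc, prec_c, vc) \
        - 0.5 * m * (d * np.log(2 * np.pi) + logdet_c)
    g[:d] -= prec_s @ vs
    g[d:] -= (vc @ prec_c).ravel()
    H[:d, :d] -= prec_s
    for j in range(m):
        sl = slice(d + j * d, d + (j + 1) * d)
        H[sl, sl] -= prec_c
    return f, g, H


def _block_mode(blk: _StateBlock, d: int, prec_s, prec_c, logdet_s, logdet_c,
                u0: np.ndarray | None = None, tol: float = 1e-11,
                max_iter: int = 100) -> tuple[np.ndarray, float, np.ndarray]:
    """Newton ascent to the block's joint posterior mode of (v_state, v_county)."""
    m = len(blk.counties)
    u = np.zeros(d + m * d) if u0 is None else u0.copy()
    f, g, H = _block_objective(blk, u, d, prec_s, prec_c, logdet_s, logdet_c)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        # Newton decrement: scale-free convergence measure (absolute
        # gradient tolerances are meaningless when the prior precision is
        # enormous in the small-variance limit)
        if 0.5 * abs(g @ step) < tol * (1.0 + abs(f)):
            break
        t = 1.0
        for _ in range(40):
            u_new = u + t * step
            f_new, g_new, H_new = _block_objective(
                blk, u_new, d, prec_s, prec_c, logdet_s, logdet_c)
            if np.isfinite(f_new) and f_new >= f - 1e-14:
                break
            t *= 0.5
        u, f, g, H = u_new, f_new, g_new, H_new
    return u, f, H


def _laplace_block(blk, d, prec_s, prec_c, logdet_s, logdet_c, warm=None):
    u, f, H = _block_mode(blk, d, prec_s, prec_c, logdet_s, logdet_c, u0=warm)
    sign, logdet = np.linalg.slogdet(-H)
    if sign <= 0:
        raise np.linalg.LinAlgError("block Hessian not negative definite at mode")
    nu = len(u)
    return f + 0.5 * nu * np.log(2 * np.pi) - 0.5 * logdet, u


def _county_integral_agq(blk, mask, vs, d, prec_c, logdet_c, nodes, logw):
    """log of the integral over one county's effect given the state effect.

    Adapted Gauss-Hermite: the grid is centered at the county's conditional
    mode with scale from the conditional Hessian.
    """
    y = blk.y[mask]
    N = blk.N[mask]
    xb = blk.xb[mask] + vs[blk.row_disease[mask]]
    dis = blk.row_disease[mask]

    def fgh(v):
        eta = xb + v[dis]
        mu = N * np.exp(eta)
        f = np.sum(y * eta - mu) - 0.5 * v @ prec_c @ v \
            - 0.5 * (d * np.log(2 * np.pi) + logdet_c)
        g = np.zeros(d)
        np.add.at(g, dis, y - mu)
        g -= prec_c @ v
        w = np.zeros(d)
        np.add.at(w, dis, mu)
        H = -np.diag(w) - prec_c
        return f, g, H

    v = np.zeros(d)
    f, g, H = fgh(v)
    for _ in range(100):
        step = np.linalg.solve(H, -g)
        if 0.5 * abs(g @ step) < 1e-12 * (1.0 + abs(f)):
            break
        t = 1.0
        for _ in range(40):
            vn = v + t * step
            fn, gn, Hn = fgh(vn)
            if np.isfinite(fn) and fn >= f - 1e-14:
                break
            t *= 0.5
        v, f, g, H = vn, fn, gn, Hn

    A = np.linalg.inv(-H)          # adaptation covariance
    L = np.linalg.cholesky(A)
    # nodes: (Q, d) raw GH abscissae products; logw: (Q,) log weight products
    pts = v + np.sqrt(2.0) * nodes @ L.T
    eta = xb[None, :] + pts[:, dis]
    logf = (
        np.sum(y * eta - N * np.exp(eta), axis=1)
        - 0.5 * np.einsum("qi,ij,qj->q", pts, prec_c, pts)
        - 0.5 * (d * np.log(2 * np.pi) + logdet_c)
    )
    t2 = np.sum(nodes * nodes, axis=1)
    return logsumexp(logw + t2 + logf) + 0.5 * d * np.log(2.0) \
        + np.sum(np.log(np.diag(L)))


def _gh_grid(d: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = hermgauss(n)
    grids = np.meshgrid(*([x] * d), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    logw = np.sum(np.log(np.stack(np.meshgrid(*([w] * d), indexing="ij"),
                                  axis=0).reshape(d, -1)), axis=0)
    return nodes, logw


def _agq_block(blk, d, prec_s, prec_c, logdet_s, logdet_c, sigma_state, n_quad):
    """Nested adaptive quadrature: outer over the state effect, inner per county."""
    # outer adaptation from the joint Laplace mode (state sub-block of the
    # profiled Hessian via Schur complement)
    u, f, H = _block_mode(blk, d, prec_s, prec_c, logdet_s, logdet_c)
    m = len(blk.counties)
    A = H[:d, :d]
    B = H[:d, d:]
    C = H[d:, d:]
    H_outer = A - B @ np.linalg.solve(C, B.T)
    cov_outer = np.linalg.inv(-H_outer)
    Ls = np.linalg.cholesky(cov_outer)
    mu_outer = u[:d]

    nodes, logw = _gh_grid(d, n_quad)
    pts = mu_outer + np.sqrt(2.0) * nodes @ Ls.T
    d_log = np.empty(len(pts))
    sign, logdet_prec_s = np.linalg.slogdet(prec_s)
    for q, vs in enumerate(pts):
        val = -0.5 * vs @ prec_s @ vs - 0.5 * (d * np.log(2 * np.pi) + logdet_s)
        for j in range(m):
            mask = blk.row_local_county == j
            val += _county_integral_agq(blk, mask, vs, d, prec_c, logdet_c,
                                        nodes, logw)
        d_log[q] = val
    t2 = np.sum(nodes * nodes, axis=1)
    return logsumexp(logw + t2 + d_log) + 0.5 * d * np.log(2.0) \
        + np.sum(np.log(np.diag(Ls)))


def marginal_loglik(
    design: DesignBundle,
    params: ParameterSet,
    method: str = "laplace",
    n_quad: int = 15,
    warm_start: dict | None = None,
) -> float:
    """Approximate log-likelihood with random effects integrated out.

    Each state contributes an independent block containing its own bivariate
    effect and those of its counties.  ``method="laplace"`` applies a joint
    Gaussian approximation at the block's posterior mode;
    ``method="adaptive_quadrature"`` nests adapted Gauss-Hermite rules
    (``n_quad`` points per dimension) over the state effect and, per node,
    over each county effect.  Deterministic for fixed inputs.  States with
    no data rows contribute exactly zero.

    ``warm_start`` may carry per-state mode vectors from a previous call at
    nearby parameters (used by the Laplace fitter); it is updated in place.
    """
    if method not in ("laplace", "adaptive_quadrature"):
        raise ValueError(f"unknown method {method!r}")
    for name, sig in (("sigma_state", params.sigma_state),
                      ("sigma_county", params.sigma_county)):
        if np.linalg.eigvalsh(sig).min() <= 0:
            raise ValidationError(f"{name} must be positive definite")
    d = params.n_diseases
    prec_s = np.linalg.inv(params.sigma_state)
    prec_c = np.linalg.inv(params.sigma_county)
    logdet_s = float(np.linalg.slogdet(params.sigma_state)[1])
    logdet_c = float(np.linalg.slogdet(params.sigma_county)[1])

    b = design.b_vector(params)
    const = float(np.sum(design.y * np.log(design.N) - gammaln(design.y + 1.0)))
    total = const
    for i, blk in enumerate(_state_blocks(design, b)):
        if len(blk.rows) == 0:
            continue
        if method == "laplace":
            warm = None if warm_start is None else warm_start.get(i)
            try:
                val, u = _laplace_block(blk, d, prec_s, prec_c, logdet_s, logdet_c,
                                        warm=warm)
            except np.linalg.LinAlgError:
                logger.warning(
                    "state block %d: Hessian not negative definite at mode; "
                    "falling back to adaptive quadrature", i)
                val = _agq_block(blk, d, prec_s, prec_c, logdet_s, logdet_c,
                                 params.sigma_state, n_quad)
                u = None
            if warm_start is not None and u is not None:
                warm_start[i] = u
        else:
            val = _agq_block(blk, d, prec_s, prec_c, logdet_s, logdet_c,
                             params.sigma_state, n_quad)
        total += val
    return float(total)


# ---------------------------------------------------------------------------
# scalar transforms to the reporting scale
# ---------------------------------------------------------------------------

def event_rate_ratio(b_j: float) -> float:
    """Multiplicative incidence-rate change per unit covariate: exp(b_j)."""
    b_j = float(b_j)
    if not np.isfinite(b_j):
        raise ValidationError("regression weight must be finite")
    return float(np.exp(b_j))


def percent_change(b_j: float) -> float:
    """Percent rate change per unit covariate: 100 (exp(b_j) - 1)."""
    return 100.0 * (event_rate_ratio(b_j) - 1.0)


def random_effect_correlation(cov: float, var1: float, var2: float) -> float:
    """Correlation implied by a covariance and two variances.

    Raises on non-positive variances or an implied |r| beyond 1 + 1e-9
    (values within the tolerance band are clipped to +/-1).
    """
    if var1 <= 0 or var2 <= 0:
        raise ValidationError("variances must be positive")
    r = float(cov) / float(np.sqrt(var1 * var2))
    if abs(r) > 1 + 1e-9:
        raise ValidationError(f"implied correlation {r:.6f} outside [-1, 1]")
    return float(np.clip(r, -1.0, 1.0))
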