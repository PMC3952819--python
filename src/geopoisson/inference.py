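"""Parameter estimation for the bivariate three-level Poisson model.

Two routes are provided:

* :func:`fit_mcmc` — Metropolis-within-Gibbs.  Each disease's fixed-effect
  block is updated by an independence Metropolis-Hastings step proposing
  from the Gaussian (Newton/IRLS) approximation of its full conditional
  given the random effects — the conditional is strictly log-concave and
  nearly Gaussian at claims-scale counts, so acceptance is high; state and
  county random-effect pairs are updated with (vectorised) bivariate random
  walks; the two covariance matrices get conjugate inverse-Wishart draws
  given the sampled effects.  "Translation" moves shift mass along the
  exact likelihood-flat ridges — intercept vs state effects, a state effect
  vs its counties' effects, and any state-/county-constant covariate column
  vs the corresponding effects — which plain random walks explore
  hopelessly slowly when only ~10-50 level-3 units identify them.

* :func:`fit_laplace` — maximum marginal likelihood with the Laplace
  approximation, quasi-Newton over (b, Cholesky-parameterised covariances),
  Wald standard errors from a finite-difference Hessian.

Empirical-Bayes random-effect prediction (:func:`empirical_bayes`) returns
the per-state joint posterior mode of the effects at fixed parameters; the
MCMC route instead reports posterior means of the sampled effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import invwishart

from . import model as _model
from .types import (
    DesignBundle,
    ModelSpec,
    ParameterSet,
    RandomEffects,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorSummary",
    "LaplaceResult",
    "fit_mcmc",
    "fit_laplace",
    "empirical_bayes",
    "summarize",
    "count_free_parameters",
]


@dataclass
class PriorSpec:
    """Weakly informative priors for the Bayesian fit.

    Each regression weight gets an independent N(0, ``b_sd``^2) prior; each
    covariance matrix an inverse-Wishart(``iw_df``, ``iw_scale`` * I) prior.
    The default scale keeps the implied variance prior diffuse across the
    range log-rate variance components actually occupy in disease-mapping
    panels (roughly 0.1 to 10); a much smaller scale would shrink the
    level-3 variance hard when only ~10 states inform it.
    """

    b_sd: float = 10.0
    iw_df: float = 3.0
    iw_scale: float = 1.0

    def validate(self, d: int) -> None:
        if self.b_sd <= 0 or self.iw_scale <= 0:
            raise ValidationError("prior scales must be positive")
        if self.iw_df < d:
            raise ValidationError(f"inverse-Wishart df must be >= dimension ({d})")


@dataclass
class ChainConfig:
    """MCMC run settings.  Proposal scales adapt during burn-in only."""

    n_iter: int = 25_000
    n_burnin: int = 5_000
    thin: int = 2
    n_chains: int = 2
    seed: int = 0
    adapt_interval: int = 1
    likelihood_power: float = 1.0  # 0 samples the prior (validation hook)
    rhat_threshold: float = 1.05

    def validate(self) -> None:
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValidationError("need 0 <= n_burnin < n_iter")
        if self.n_chains < 1 or self.thin < 1:
            raise ValidationError("need n_chains >= 1 and thin >= 1")


@dataclass
class PosteriorSummary:
    """Table-style posterior summaries plus empirical-Bayes effects."""

    fixed_effects: pd.DataFrame
    random_effect_summary: pd.DataFrame
    eb: RandomEffects
    rhat: pd.Series | None
    converged: bool
    n_draws: int

    @property
    def p_floor(self) -> float:
        return 2.0 / self.n_draws


@dataclass
class LaplaceResult:
    params: ParameterSet
    se: pd.Series
    loglik: float
    converged: bool
    n_iter: int


def count_free_parameters(spec: ModelSpec) -> int:
    """Fixed-effect weights plus d(d+1)/2 covariance parameters per level."""
    d = spec.n_diseases
    return spec.n_fixed_effects + 2 * (d * (d + 1) // 2)


# ---------------------------------------------------------------------------
# fixed-effects-only ridge IRLS (initialisation / "analytic" start)
# ---------------------------------------------------------------------------

def _ridge_irls(X, y, log_offset, ridge=1e-6, max_iter=100, tol=1e-10):
    """Poisson GLM (log link, offset) by damped IRLS with a ridge.

    ``ridge`` may be a scalar or a per-column vector of penalty precisions;
    a small floor keeps the solve well posed when a centered policy column
    is constant (e.g. every synthetic state shares a code).
    """
    n, p = X.shape
    ridge = np.broadcast_to(np.asarray(ridge, float), (p,)).copy()
    b = np.zeros(p)
    eta = X @ b
    mu = np.exp(np.clip(eta + log_offset, -700, 700))
    dev = -np.sum(y * eta - mu)
    for it in range(max_iter):
        W = mu
        g = X.T @ (y - mu) - ridge * b
        H = (X * W[:, None]).T @ X + np.diag(ridge)
        step = np.linalg.solve(H, g)
        t = 1.0
        for _ in range(40):
            b_new = b + t * step
            eta = X @ b_new
            mu = np.exp(np.clip(eta + log_offset, -700, 700))
            dev_new = -np.sum(y * eta - mu) + 0.5 * b_new @ (ridge * b_new)
            if np.isfinite(dev_new) and dev_new <= dev + 1e-12:
                break
            t *= 0.5
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            dev = dev_new
            break
        b, dev = b_new, dev_new
    fisher = (X * mu[:, None]).T @ X + np.diag(ridge)
    return b, fisher


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed index structure shared by all chains."""

    def __init__(self, design: DesignBundle):
        self.design = design
        self.d = design.n_diseases
        self.p = design.X.shape[1]
        self.n_c = design.n_counties
        self.n_s = design.n_states
        self.rows_k = [np.flatnonzero(design.row_disease == k) for k in range(self.d)]
        self.cols_k = [np.flatnonzero(design.col_disease == k) for k in range(self.d)]
        self.Xk = [np.ascontiguousarray(design.X[np.ix_(r, c)])
                   for r, c in zip(self.rows_k, self.cols_k)]
        self.int_pos = []  # position of each disease's intercept within its block
        for k, dname in enumerate(design.spec.diseases):
            lbl = f"{dname}:Intercept"
            block = [design.col_labels[j] for j in self.cols_k[k]]
            self.int_pos.append(block.index(lbl))
        logN = np.log(design.N)
        # translation-move bookkeeping: columns whose value is constant
        # within every county (-> county-paired ridge) or every state
        # (-> state-paired ridge).  The intercept pairs with the state level.
        self.trans: list[list[tuple[int, str, np.ndarray]]] = []
        for k in range(self.d):
            rows, cols = self.rows_k[k], self.cols_k[k]
            cty = design.row_county[rows]
            moves = []
            for pos, j in enumerate(cols):
                colv = design.X[rows, j]
                per_county = np.full(self.n_c, np.nan)
                per_county[cty] = colv
                if not np.array_equal(per_county[cty], colv):
                    continue  # varies within a county (e.g. Gender)
                per_county = np.nan_to_num(per_county)
                per_state = np.full(self.n_s, np.nan)
                per_state[design.county_state] = per_county
                state_const = all(
                    np.ptp(per_county[design.county_state == s]) == 0
                    for s in range(self.n_s)
                    if np.any(design.county_state == s))
                if state_const:
                    moves.append((pos, "state", np.nan_to_num(per_state)))
                else:
                    moves.append((pos, "county", per_county))
            self.trans.append(moves)
        # joint cross-disease ridge moves: the same covariate column in both
        # disease blocks, shifted together with a proposal shaped like the
        # level's covariance (the effects are strongly correlated across
        # diseases, so single-disease ridge moves stall)
        self.trans_joint: list[tuple[np.ndarray, str, np.ndarray]] = []
        if self.d == 2:
            by_name = []
            for k in range(self.d):
                names = {}
                for pos, level, xvals in self.trans[k]:
                    lbl = design.col_labels[self.cols_k[k][pos]].split(":", 1)[1]
                    names[lbl] = (pos, level, xvals)
                by_name.append(names)
            for lbl, (pos0, level0, x0) in by_name[0].items():
                if lbl in by_name[1]:
                    pos1, level1, x1 = by_name[1][lbl]
                    if level0 == level1 and np.array_equal(x0, x1):
                        cols = np.array([self.cols_k[0][pos0],
                                         self.cols_k[1][pos1]])
                        self.trans_joint.append((cols, level0, x0))

        # initial weights: state-constant columns (other than the
        # intercepts) are ridge-penalised in the init GLM so the level-3
        # variation starts in the state effects rather than being absorbed
        # into the handful of policy contrasts
        ridge = np.full(self.p, 1e-6)
        for k in range(self.d):
            for pos, level, _ in self.trans[k]:
                j = self.cols_k[k][pos]
                if level == "state" and pos != self.int_pos[k]:
                    ridge[j] = 4.0
        b0, _ = _ridge_irls(design.X, design.y.astype(float), logN, ridge=ridge)
        self.b_init = b0

        # crude residual log-rates per (county, disease) for effect inits
        mu0 = design.N * np.exp(np.clip(design.X @ b0, -700, 700))
        num = np.zeros((self.n_c, self.d))
        den = np.zeros((self.n_c, self.d))
        np.add.at(num, (design.row_county, design.row_disease), design.y)
        np.add.at(den, (design.row_county, design.row_disease), mu0)
        r_cd = np.log((num + 0.5) / (den + 0.5))
        vs0 = np.zeros((self.n_s, self.d))
        cnt = np.zeros(self.n_s)
        np.add.at(vs0, design.county_state, r_cd)
        np.add.at(cnt, design.county_state, 1.0)
        vs0 /= np.maximum(cnt, 1.0)[:, None]
        self.v_state_init = vs0
        self.v_county_init = r_cd - vs0[design.county_state]
        self.sigma_state_init = np.cov(vs0.T, ddof=1) + 0.05 * np.eye(self.d) \
            if self.n_s > 1 else np.eye(self.d)
        self.sigma_county_init = (np.cov(self.v_county_init.T, ddof=1)
                                  + 0.05 * np.eye(self.d)
                                  if self.n_c > 1 else np.eye(self.d))


def _conditional_newton(Xk, yk, off_k, b_cur, prior_prec, pw,
                        max_iter=50, tol=1e-9):
    """Mode and Fisher factor of a disease block's full conditional.

    The conditional log-density (likelihood tempered by ``pw``) is
    pw * sum(y eta - N exp(eta + off)) - b'b/(2 b_var); Newton from the
    current b converges in a few steps.  Returns (mode, chol(Fisher)).
    """
    b = b_cur.copy()
    eta = Xk @ b
    mu = np.exp(np.clip(eta + off_k, -700, 700))  # off_k includes log N
    obj = pw * (yk @ eta - mu.sum()) - 0.5 * prior_prec * b @ b
    I = np.eye(len(b))
    for _ in range(max_iter):
        g = pw * (Xk.T @ (yk - mu)) - prior_prec * b
        F = pw * ((Xk * mu[:, None]).T @ Xk) + prior_prec * I
        L = np.linalg.cholesky(F)
        step = np.linalg.solve(F, g)
        t = 1.0
        for _ in range(40):
            b_new = b + t * step
            eta = Xk @ b_new
            mu = np.exp(np.clip(eta + off_k, -700, 700))
            obj_new = pw * (yk @ eta - mu.sum()) - 0.5 * prior_prec * b_new @ b_new
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            t *= 0.5
        done = np.max(np.abs(b_new - b)) < tol
        b, obj = b_new, obj_new
        if done:
            break
    g = pw * (Xk.T @ (yk - mu)) - prior_prec * b
    F = pw * ((Xk * mu[:, None]).T @ Xk) + prior_prec * I
    return b, np.linalg.cholesky(F)


def _quad_forms(v: np.ndarray, prec: np.ndarray) -> np.ndarray:
    return np.einsum("ij,jk,ik->i", v, prec, v)


def _run_chain(ws: _Workspace, priors: PriorSpec, cfg: ChainConfig, seed_key) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed,
                                                       spawn_key=seed_key))
    design = ws.design
    d, p, n_c, n_s = ws.d, ws.p, ws.n_c, ws.n_s
    y = design.y.astype(float)
    N = design.N
    row_c, row_s, row_k = design.row_county, design.row_state, design.row_disease
    pw = cfg.likelihood_power
    b_var = priors.b_sd ** 2
    S0 = priors.iw_scale * np.eye(d)
    df0 = priors.iw_df

    # state
    b = ws.b_init.copy()
    vs = ws.v_state_init.copy()
    vc = ws.v_county_init.copy()
    sig_s = np.atleast_2d(ws.sigma_state_init).copy()
    sig_c = np.atleast_2d(ws.sigma_county_init).copy()
    prec_s = np.linalg.inv(sig_s)
    prec_c = np.linalg.inv(sig_c)
    eta = design.X @ b + vs[row_s, row_k] + vc[row_c, row_k]
    mu = N * np.exp(eta)

    # adaptive proposal log-scales
    ls_c = np.full(n_c, np.log(0.5))
    ls_s = np.full(n_s, np.log(0.5))
    ls_tr = [np.full(len(ws.trans[k]), np.log(0.5)) for k in range(d)]
    ls_rw = np.full(d, np.log(0.3))
    ls_tj = np.full(len(ws.trans_joint), np.log(0.5))
    ls_swB = np.full(d, np.log(0.5))
    logN_rows = np.log(N)

    n_keep = (cfg.n_iter - cfg.n_burnin) // cfg.thin
    out_b = np.empty((n_keep, p))
    out_ss = np.empty((n_keep, d, d))
    out_sc = np.empty((n_keep, d, d))
    sum_vs = np.zeros((n_s, d))
    sum_vs2 = np.zeros((n_s, d))
    sum_vc = np.zeros((n_c, d))
    sum_vc2 = np.zeros((n_c, d))
    kept = 0
    n_prop_b = np.zeros(d)
    n_acc_b = np.zeros(d)

    with np.errstate(over="ignore", invalid="ignore"):
        for it in range(cfg.n_iter):
            adapting = it < cfg.n_burnin
            gam = 1.0 / (1.0 + it) ** 0.6

            # --- fixed-effect blocks: conditional-mode independence MH --
            for k in range(d):
                rows, cols = ws.rows_k[k], ws.cols_k[k]
                off_k = (logN_rows[rows] + vs[row_s[rows], k] + vc[row_c[rows], k])
                try:
                    b_star, L = _conditional_newton(
                        ws.Xk[k], y[rows], off_k, b[cols], 1.0 / b_var, pw)
                except np.linalg.LinAlgError:
                    continue
                z = rng.standard_normal(len(cols))
                b_prop = b_star + np.linalg.solve(L.T, z)
                xb_prop = ws.Xk[k] @ b_prop
                mu_prop = np.exp(np.clip(xb_prop + off_k, -700, 700))
                v_part = off_k - logN_rows[rows]
                xb_cur = eta[rows] - v_part

                def _logq(bv):
                    r = L.T @ (bv - b_star)
                    return -0.5 * r @ r  # up to the shared normalising constant

                lp_prop = pw * (y[rows] @ xb_prop - mu_prop.sum()) \
                    - (b_prop @ b_prop) / (2 * b_var)
                lp_cur = pw * (y[rows] @ xb_cur - mu[rows].sum()) \
                    - (b[cols] @ b[cols]) / (2 * b_var)
                lr = (lp_prop - lp_cur) - (_logq(b_prop) - _logq(b[cols]))
                n_prop_b[k] += 1
                if np.isfinite(lr) and np.log(rng.random()) < lr:
                    n_acc_b[k] += 1
                    b[cols] = b_prop
                    eta[rows] = xb_prop + v_part
                    mu[rows] = mu_prop

                # preconditioned random-walk companion step: escapes the
                # skewed-tail states where the independence proposal stalls
                z = rng.standard_normal(len(cols))
                b_prop = b[cols] + np.exp(ls_rw[k]) * np.linalg.solve(L.T, z)
                xb_prop = ws.Xk[k] @ b_prop
                mu_prop = np.exp(np.clip(xb_prop + off_k, -700, 700))
                xb_cur = eta[rows] - v_part
                lr = (pw * (y[rows] @ (xb_prop - xb_cur)
                            - (mu_prop.sum() - mu[rows].sum()))
                      - (b_prop @ b_prop - b[cols] @ b[cols]) / (2 * b_var))
                acc = np.isfinite(lr) and np.log(rng.random()) < lr
                if acc:
                    b[cols] = b_prop
                    eta[rows] = xb_prop + v_part
                    mu[rows] = mu_prop
                if adapting:
                    ls_rw[k] += gam * ((1.0 if acc else 0.0) - 0.234)

            # --- county random effects (vectorised over counties) ------
            # proposal shaped by the current covariance: the conditional
            # geometry is highly anisotropic when the cross-disease
            # correlation is near 1
            A_c = np.linalg.cholesky(sig_c)
            delta_c = np.exp(ls_c)[:, None] * (rng.standard_normal((n_c, d)) @ A_c.T)
            d_eta = delta_c[row_c, row_k]
            mu_new = N * np.exp(eta + d_eta)
            d_row = pw * (y * d_eta - (mu_new - mu))
            d_pois = np.bincount(row_c, weights=d_row, minlength=n_c)
            vc_new = vc + delta_c
            d_prior = -0.5 * (_quad_forms(vc_new, prec_c) - _quad_forms(vc, prec_c))
            lr = d_pois + d_prior
            acc_c = np.log(rng.random(n_c)) < np.where(np.isfinite(lr), lr, -np.inf)
            if acc_c.any():
                vc[acc_c] = vc_new[acc_c]
                rows_acc = acc_c[row_c]
                eta[rows_acc] += d_eta[rows_acc]
                mu[rows_acc] = mu_new[rows_acc]
            if adapting:
                ls_c += gam * (acc_c.astype(float) - 0.3)

            # --- state random effects ----------------------------------
            A_s = np.linalg.cholesky(sig_s)
            delta_s = np.exp(ls_s)[:, None] * (rng.standard_normal((n_s, d)) @ A_s.T)
            d_eta = delta_s[row_s, row_k]
            mu_new = N * np.exp(eta + d_eta)
            d_row = pw * (y * d_eta - (mu_new - mu))
            d_pois = np.bincount(row_s, weights=d_row, minlength=n_s)
            vs_new = vs + delta_s
            d_prior = -0.5 * (_quad_forms(vs_new, prec_s) - _quad_forms(vs, prec_s))
            lr = d_pois + d_prior
            acc_s = np.log(rng.random(n_s)) < np.where(np.isfinite(lr), lr, -np.inf)
            if acc_s.any():
                vs[acc_s] = vs_new[acc_s]
                rows_acc = acc_s[row_s]
                eta[rows_acc] += d_eta[rows_acc]
                mu[rows_acc] = mu_new[rows_acc]
            if adapting:
                ls_s += gam * (acc_s.astype(float) - 0.3)

            # --- translation moves: column <-> effect-level ridges -----
            # Shifting a state-/county-constant column's weight by delta
            # while subtracting delta * (column value) from the paired
            # effects leaves eta (hence the likelihood) exactly unchanged;
            # the priors alone decide acceptance.
            for k in range(d):
                for t_idx, (pos, level, xvals) in enumerate(ws.trans[k]):
                    delta = np.exp(ls_tr[k][t_idx]) * rng.standard_normal()
                    j = ws.cols_k[k][pos]
                    b_new_j = b[j] + delta
                    if level == "state":
                        v_new = vs.copy()
                        v_new[:, k] -= delta * xvals
                        d_prior_v = -0.5 * (_quad_forms(v_new, prec_s).sum()
                                            - _quad_forms(vs, prec_s).sum())
                    else:
                        v_new = vc.copy()
                        v_new[:, k] -= delta * xvals
                        d_prior_v = -0.5 * (_quad_forms(v_new, prec_c).sum()
                                            - _quad_forms(vc, prec_c).sum())
                    lr = -(b_new_j ** 2 - b[j] ** 2) / (2 * b_var) + d_prior_v
                    acc = np.isfinite(lr) and np.log(rng.random()) < lr
                    if acc:
                        b[j] = b_new_j
                        if level == "state":
                            vs = v_new
                        else:
                            vc = v_new
                    if adapting:
                        ls_tr[k][t_idx] += gam * ((1.0 if acc else 0.0) - 0.44)

            # --- joint cross-disease ridge moves -----------------------
            for t_idx, (cols_j, level, xvals) in enumerate(ws.trans_joint):
                sig = sig_s if level == "state" else sig_c
                A = np.linalg.cholesky(sig)
                delta = np.exp(ls_tj[t_idx]) * (A @ rng.standard_normal(d))
                b_new = b[cols_j] + delta
                if level == "state":
                    v_new = vs - np.outer(xvals, delta)
                    d_prior_v = -0.5 * (_quad_forms(v_new, prec_s).sum()
                                        - _quad_forms(vs, prec_s).sum())
                else:
                    v_new = vc - np.outer(xvals, delta)
                    d_prior_v = -0.5 * (_quad_forms(v_new, prec_c).sum()
                                        - _quad_forms(vc, prec_c).sum())
                lr = -(b_new @ b_new - b[cols_j] @ b[cols_j]) / (2 * b_var) \
                    + d_prior_v
                acc = np.isfinite(lr) and np.log(rng.random()) < lr
                if acc:
                    b[cols_j] = b_new
                    if level == "state":
                        vs = v_new
                    else:
                        vc = v_new
                if adapting:
                    ls_tj[t_idx] += gam * ((1.0 if acc else 0.0) - 0.30)

            # --- translation move B: state <-> its counties ------------
            for k in range(d):
                delta = np.exp(ls_swB[k]) * rng.standard_normal(n_s)
                vs_new = vs.copy()
                vs_new[:, k] += delta
                vc_new = vc.copy()
                vc_new[:, k] -= delta[design.county_state]
                d_prior_s = -0.5 * (_quad_forms(vs_new, prec_s) - _quad_forms(vs, prec_s))
                d_prior_c = -0.5 * np.bincount(
                    design.county_state,
                    weights=_quad_forms(vc_new, prec_c) - _quad_forms(vc, prec_c),
                    minlength=n_s,
                )
                lr = d_prior_s + d_prior_c
                acc = np.log(rng.random(n_s)) < np.where(np.isfinite(lr), lr, -np.inf)
                if acc.any():
                    vs[acc, k] = vs_new[acc, k]
                    acc_cty = acc[design.county_state]
                    vc[acc_cty, k] = vc_new[acc_cty, k]
                if adapting:
                    ls_swB[k] += gam * (acc.mean() - 0.44)

            # --- conjugate inverse-Wishart covariance updates ----------
            sig_s = invwishart.rvs(df=df0 + n_s, scale=S0 + vs.T @ vs,
                                   random_state=rng)
            sig_c = invwishart.rvs(df=df0 + n_c, scale=S0 + vc.T @ vc,
                                   random_state=rng)
            sig_s = np.atleast_2d(sig_s)
            sig_c = np.atleast_2d(sig_c)
            prec_s = np.linalg.inv(sig_s)
            prec_c = np.linalg.inv(sig_c)

            if not adapting and (it - cfg.n_burnin) % cfg.thin == 0:
                out_b[kept] = b
                out_ss[kept] = sig_s
                out_sc[kept] = sig_c
                sum_vs += vs
                sum_vs2 += vs * vs
                sum_vc += vc
                sum_vc2 += vc * vc
                kept += 1

    if not np.isfinite(out_b[:kept]).all():
        raise RuntimeError("divergent chain: non-finite draws; "
                           "dump: last b=%r" % (b,))
    n_eff = max(kept, 1)
    return {
        "b": out_b[:kept],
        "sigma_state": out_ss[:kept],
        "sigma_county": out_sc[:kept],
        "v_state_mean": sum_vs / n_eff,
        "v_state_sd": np.sqrt(np.maximum(sum_vs2 / n_eff - (sum_vs / n_eff) ** 2, 0)),
        "v_county_mean": sum_vc / n_eff,
        "v_county_sd": np.sqrt(np.maximum(sum_vc2 / n_eff - (sum_vc / n_eff) ** 2, 0)),
        "accept_rate_b": n_acc_b / np.maximum(n_prop_b, 1),
    }


def fit_mcmc(
    design: DesignBundle,
    priors: PriorSpec | None = None,
    chain: ChainConfig | None = None,
) -> tuple[dict, PosteriorSummary]:
    """Run the Metropolis-within-Gibbs sampler and summarise the draws.

    Returns ``(samples, summary)``: ``samples`` holds per-chain arrays —
    ``b`` (chains, draws, p), ``sigma_state`` / ``sigma_county``
    (chains, draws, d, d) — plus running means/SDs of the random effects and
    metadata; ``summary`` is the report-style
    :class:`PosteriorSummary`.  Deterministic for a fixed seed.
    """
    priors = priors or PriorSpec()
    cfg = chain or ChainConfig()
    priors.validate(design.n_diseases)
    cfg.validate()
    ws = _Workspace(design)
    chains = [_run_chain(ws, priors, cfg, seed_key=(c,)) for c in range(cfg.n_chains)]
    samples = {
        "b": np.stack([c["b"] for c in chains]),
        "sigma_state": np.stack([c["sigma_state"] for c in chains]),
        "sigma_county": np.stack([c["sigma_county"] for c in chains]),
        "v_state_mean": np.stack([c["v_state_mean"] for c in chains]),
        "v_state_sd": np.stack([c["v_state_sd"] for c in chains]),
        "v_county_mean": np.stack([c["v_county_mean"] for c in chains]),
        "v_county_sd": np.stack([c["v_county_sd"] for c in chains]),
        "col_labels": list(design.col_labels),
        "diseases": list(design.spec.diseases),
        "state_ids": design.state_ids,
        "county_ids": design.county_ids,
        "rhat_threshold": cfg.rhat_threshold,
    }
    summary = summarize(samples)
    return samples, summary


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _mcmc_p(draws: np.ndarray) -> float:
    m = draws.size
    frac_pos = np.mean(draws > 0)
    frac_neg = np.mean(draws < 0)
    return float(max(2 * min(frac_pos, frac_neg), 2.0 / m))


def summarize(samples: dict) -> PosteriorSummary:
    """Posterior means, equal-tailed 95% CIs, rate transforms and p-values.

    Rate columns are exponentials of the *estimate* columns — the rate CI is
    exp applied to the estimate CI endpoints, never the mean of per-draw
    exponentials.  The p-value is the two-sided posterior tail fraction with
    floor 2/M.  Requires at least 100 retained draws.
    """
    b = np.asarray(samples["b"])
    if b.ndim != 3:
        raise ValidationError("samples['b'] must be (chains, draws, p)")
    n_chains, m_per, p = b.shape
    M = n_chains * m_per
    if M < 100:
        raise ValidationError(f"too few retained draws ({M} < 100)")
    labels = list(samples["col_labels"])
    pooled = b.reshape(M, p)

    est = pooled.mean(axis=0)
    lo = np.percentile(pooled, 2.5, axis=0)
    hi = np.percentile(pooled, 97.5, axis=0)
    fixed = pd.DataFrame({
        "parameter": labels,
        "estimate": est,
        "ci_lower": lo,
        "ci_upper": hi,
        "rate": np.exp(est),
        "rate_ci_lower": np.exp(lo),
        "rate_ci_upper": np.exp(hi),
        "posterior_sd": pooled.std(axis=0, ddof=1),
        "p_value": [_mcmc_p(pooled[:, j]) for j in range(p)],
    })

    rows = []
    diseases = list(samples["diseases"])
    d = len(diseases)
    for level in ("state", "county"):
        sig = np.asarray(samples[f"sigma_{level}"]).reshape(M, d, d)
        for i in range(d):
            for j in range(i, d):
                draws = sig[:, i, j]
                rec = {
                    "level": level,
                    "pair": f"{diseases[i]}:{diseases[j]}",
                    "estimate": draws.mean(),
                    "ci_lower": np.percentile(draws, 2.5),
                    "ci_upper": np.percentile(draws, 97.5),
                    "posterior_sd": draws.std(ddof=1),
                }
                if i == j:
                    rec.update(correlation=1.0, correlation_sd=0.0)
                else:
                    r = sig[:, i, j] / np.sqrt(sig[:, i, i] * sig[:, j, j])
                    rec.update(
                        correlation=_model.random_effect_correlation(
                            draws.mean(),
                            sig[:, i, i].mean(),
                            sig[:, j, j].mean(),
                        ),
                        correlation_mean=r.mean(),
                        correlation_sd=r.std(ddof=1),
                        correlation_ci_lower=np.percentile(r, 2.5),
                        correlation_ci_upper=np.percentile(r, 97.5),
                    )
                rows.append(rec)
    re_summary = pd.DataFrame(rows)

    vs = np.asarray(samples["v_state_mean"]).mean(axis=0)
    vc = np.asarray(samples["v_county_mean"]).mean(axis=0)
    eb = RandomEffects(
        v_state=pd.DataFrame(vs, index=list(samples["state_ids"]), columns=diseases),
        v_county=pd.DataFrame(vc, index=list(samples["county_ids"]), columns=diseases),
    )

    rhat = None
    converged = True
    if n_chains >= 2:
        data = {"b": b}
        for level in ("state", "county"):
            sig = np.asarray(samples[f"sigma_{level}"])
            iu = np.triu_indices(d)
            tri = sig[:, :, iu[0], iu[1]]
            data[f"sigma_{level}"] = tri.reshape(n_chains, m_per, -1)
        ds = az.convert_to_dataset({k: v for k, v in data.items()})
        rh = az.rhat(ds)
        vals = {}
        for j, lbl in enumerate(labels):
            vals[lbl] = float(rh["b"].values[j])
        for level in ("state", "county"):
            for j in range(data[f"sigma_{level}"].shape[-1]):
                vals[f"sigma_{level}[{j}]"] = float(rh[f"sigma_{level}"].values[j])
        rhat = pd.Series(vals)
        threshold = samples.get("rhat_threshold", 1.05)
        converged = bool((rhat < threshold).all())
        if not converged:
            logger.warning("summaries emitted with convergence warning: "
                           "max R-hat %.3f", rhat.max())

    return PosteriorSummary(
        fixed_effects=fixed,
        random_effect_summary=re_summary,
        eb=eb,
        rhat=rhat,
        converged=converged,
        n_draws=M,
    )


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------

def empirical_bayes(design: DesignBundle, params: ParameterSet) -> RandomEffects:
    """Joint posterior mode of the random effects at fixed parameters.

    Computed per state block by Newton ascent (the same inner problem the
    Laplace marginal uses).  Counties or states with no data shrink exactly
    to zero.
    """
    design.subset_params(params)
    d = params.n_diseases
    prec_s = np.linalg.inv(params.sigma_state)
    prec_c = np.linalg.inv(params.sigma_county)
    logdet_s = float(np.linalg.slogdet(params.sigma_state)[1])
    logdet_c = float(np.linalg.slogdet(params.sigma_county)[1])
    b = design.b_vector(params)
    vs = np.zeros((design.n_states, d))
    vc = np.zeros((design.n_counties, d))
    for i, blk in enumerate(_model._state_blocks(design, b)):
        if len(blk.rows) == 0:
            continue
        u, _, _ = _model._block_mode(blk, d, prec_s, prec_c, logdet_s, logdet_c)
        vs[i] = u[:d]
        vc[blk.counties] = u[d:].reshape(len(blk.counties), d)
    diseases = list(design.spec.diseases)
    return RandomEffects(
        v_state=pd.DataFrame(vs, index=list(design.state_ids), columns=diseases),
        v_county=pd.DataFrame(vc, index=list(design.county_ids), columns=diseases),
    )


# ---------------------------------------------------------------------------
# Laplace maximum likelihood
# ---------------------------------------------------------------------------

def _nearest_pd(S: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    return (V * np.maximum(w, floor)) @ V.T


def _chol_unpack(theta: np.ndarray, d: int) -> np.ndarray:
    """Lower-triangular L from [log l_11, l_21, log l_22, ...] packing."""
    L = np.zeros((d, d))
    t = 0
    for i in range(d):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[t])
            else:
                L[i, j] = theta[t]
            t += 1
    return L


def _chol_pack(sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(sigma)
    d = sigma.shape[0]
    out = []
    for i in range(d):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def fit_laplace(
    design: DesignBundle,
    start: ParameterSet | str = "auto",
    max_iter: int = 300,
    compute_se: bool = True,
    gtol: float = 1e-6,
    fix_sigma: tuple[np.ndarray, np.ndarray] | None = None,
) -> LaplaceResult:
    """Maximise the Laplace-approximated marginal likelihood.

    ``start="auto"`` initialises the weights at the fixed-effects-only
    (ridge IRLS) solution and both covariances at 0.1 * I.  Optimisation is
    L-BFGS-B over (b, log-Cholesky covariance factors); covariance diagonals
    are bounded in [1e-8, ~900] on the variance scale.  Wald standard errors
    come from a central finite-difference Hessian at the optimum (delta
    method back to variance/covariance scale for the Sigma entries).

    ``fix_sigma=(sigma_state, sigma_county)`` holds both covariance
    matrices fixed and profiles only the weights — e.g. to evaluate the
    degenerate zero-variance limit, where the fit reduces to a plain
    Poisson regression.
    """
    d = design.n_diseases
    p = design.X.shape[1]
    q = d * (d + 1) // 2

    if fix_sigma is not None:
        return _fit_laplace_fixed_sigma(design, fix_sigma, max_iter,
                                        compute_se, gtol)

    b0, fisher0 = _ridge_irls(design.X, design.y.astype(float), np.log(design.N))
    if start == "auto":
        ws = _Workspace(design)
        b0 = ws.b_init
        s_s0 = _nearest_pd(np.atleast_2d(ws.sigma_state_init))
        s_c0 = _nearest_pd(np.atleast_2d(ws.sigma_county_init))
        th0 = np.concatenate([b0, _chol_pack(s_s0), _chol_pack(s_c0)])
    else:
        design.subset_params(start)
        th0 = np.concatenate([
            design.b_vector(start),
            _chol_pack(start.sigma_state),
            _chol_pack(start.sigma_county),
        ])

    warm: dict = {}
    diag_idx = []
    t = p
    for i in range(d):
        for j in range(i + 1):
            if i == j:
                diag_idx.append(t)
            t += 1
    for i in range(d):
        for j in range(i + 1):
            if i == j:
                diag_idx.append(t)
            t += 1

    def unpack(theta):
        b = pd.Series(theta[:p], index=design.col_labels)
        Ls = _chol_unpack(theta[p:p + q], d)
        Lc = _chol_unpack(theta[p + q:], d)
        return ParameterSet(b=b, sigma_state=Ls @ Ls.T, sigma_county=Lc @ Lc.T)

    def neg_ll(theta):
        try:
            return -_model.marginal_loglik(design, unpack(theta),
                                           method="laplace", warm_start=warm)
        except (np.linalg.LinAlgError, ValidationError):
            return 1e12

    # precondition: weight coordinates carry curvature up to ~1e5 while the
    # covariance coordinates carry ~1; optimise in GLM-standard-error units
    scale = np.ones(p + 2 * q)
    se0 = np.sqrt(np.clip(np.diag(np.linalg.inv(fisher0)), 1e-12, 100.0))
    scale[:p] = np.minimum(se0, 10.0)

    def neg_ll_scaled(x):
        return neg_ll(x * scale)

    bounds = [(None, None)] * (p + 2 * q)
    for idx in range(p, p + 2 * q):
        if idx in diag_idx:
            bounds[idx] = (np.log(1e-4) / scale[idx], np.log(30.0) / scale[idx])
        else:
            bounds[idx] = (-10.0 / scale[idx], 10.0 / scale[idx])

    res = optimize.minimize(
        neg_ll_scaled, th0 / scale, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "eps": 1e-4, "gtol": gtol,
                 "ftol": 1e-13, "maxfun": 50 * max_iter},
    )
    theta = res.x * scale
    params = unpack(theta)
    if not res.success:
        logger.warning("Laplace fit did not converge: %s", res.message)

    names = []
    diseases = list(design.spec.diseases)
    for level in ("state", "county"):
        for i in range(d):
            for j in range(i + 1):
                names.append(f"sigma_{level}[{diseases[i]},{diseases[j]}]")
    se_vals = np.full(p + 2 * q, np.nan)
    se_sig = np.full(2 * q, np.nan)
    if compute_se:
        # Hessian in the preconditioned coordinates (curvature ~O(1) there,
        # so a fixed step is numerically safe), then map back
        H_s = _fd_hessian(neg_ll_scaled, res.x, step=5e-3)
        try:
            cov_s = np.linalg.inv(H_s)
            cov_th = (cov_s * scale).T * scale  # S cov S
            se_vals = np.sqrt(np.clip(np.diag(cov_th), 0, None))
            jac = _fd_jacobian(
                lambda t: _sigma_entries(t, d, q), theta[p:], step=1e-6)
            cov_sig = jac @ cov_th[p:, p:] @ jac.T
            se_sig = np.sqrt(np.clip(np.diag(cov_sig), 0, None))
        except np.linalg.LinAlgError:
            logger.warning("Hessian singular; standard errors unavailable")
    se = pd.concat([
        pd.Series(se_vals[:p], index=design.col_labels),
        pd.Series(se_sig, index=names),
    ])

    return LaplaceResult(
        params=params, se=se, loglik=float(-res.fun),
        converged=bool(res.success), n_iter=int(res.nit),
    )


def _fit_laplace_fixed_sigma(design, fix_sigma, max_iter, compute_se, gtol):
    d = design.n_diseases
    p = design.X.shape[1]
    S_s = np.atleast_2d(np.asarray(fix_sigma[0], float))
    S_c = np.atleast_2d(np.asarray(fix_sigma[1], float))
    warm: dict = {}
    b0, fisher0 = _ridge_irls(design.X, design.y.astype(float), np.log(design.N))
    scale = np.sqrt(np.clip(np.diag(np.linalg.inv(fisher0)), 1e-12, 100.0))
    scale = np.minimum(scale, 10.0)

    def neg_ll(bvec):
        params = ParameterSet(b=pd.Series(bvec, index=design.col_labels),
                              sigma_state=S_s, sigma_county=S_c)
        try:
            return -_model.marginal_loglik(design, params, method="laplace",
                                           warm_start=warm)
        except (np.linalg.LinAlgError, ValidationError):
            return 1e12

    res = optimize.minimize(
        lambda x: neg_ll(x * scale), b0 / scale, method="L-BFGS-B",
        options={"maxiter": max_iter, "eps": 1e-4, "gtol": gtol,
                 "ftol": 1e-13, "maxfun": 50 * max_iter},
    )
    bhat = res.x * scale
    params = ParameterSet(b=pd.Series(bhat, index=design.col_labels),
                          sigma_state=S_s, sigma_county=S_c)
    se_vals = np.full(p, np.nan)
    if compute_se:
        H = _fd_hessian(neg_ll, bhat, step=1e-5)
        try:
            se_vals = np.sqrt(np.clip(np.diag(np.linalg.inv(H)), 0, None))
        except np.linalg.LinAlgError:
            logger.warning("Hessian singular; standard errors unavailable")
    return LaplaceResult(
        params=params, se=pd.Series(se_vals, index=design.col_labels),
        loglik=float(-res.fun), converged=bool(res.success), n_iter=int(res.nit),
    )


def _sigma_entries(theta_sig: np.ndarray, d: int, q: int) -> np.ndarray:
    Ls = _chol_unpack(theta_sig[:q], d)
    Lc = _chol_unpack(theta_sig[q:], d)
    out = []
    for L in (Ls, Lc):
        S = L @ L.T
        for i in range(d):
            for j in range(i + 1):
                out.append(S[i, j])
    return np.array(out)


def _fd_hessian(f, x, step=1e-4):
    n = len(x)
    H = np.empty((n, n))
    hs = step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += hs[i]; xpp[j] += hs[j]
            xpm = x.copy(); xpm[i] += hs[i]; xpm[j] -= hs[j]
            xmp = x.copy(); xmp[i] -= hs[i]; xmp[j] += hs[j]
            xmm = x.copy(); xmm[i] -= hs[i]; xmm[j] -= hs[j]
            H[i, j] = H[j, i] = (
                f(xpp) - f(xpm) - f(xmp) + f(xmm)
            ) / (4 * hs[i] * hs[j])
    return H


def _fd_jacobian(f, x, step=1e-6):
    f0 = f(x)
    J = np.empty((len(f0), len(x)))
    for i in range(len(x)):
        xp = x.copy(); xp[i] += step
        xm = x.copy(); xm[i] -= step
        J[:, i] = (f(xp) - f(xm)) / (2 * step)
    return J
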