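"""Scikit-learn-style estimator facade over the two fitting routes.

Both estimators follow the sklearn contract — constructor stores
hyper-parameters verbatim, ``fit`` returns ``self``, fitted state lives in
trailing-underscore attributes, ``get_params`` / ``set_params`` come from
``BaseEstimator`` — so they compose with sklearn model-selection tooling.
``fit`` takes a :class:`~geopoisson.types.DesignBundle` (the model's
canonical input container) in place of a plain feature matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

try:  # sklearn is optional at run time; fall back to a minimal base class
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:
        def get_params(self, deep=True):
            import inspect
            keys = inspect.signature(self.__init__).parameters
            return {k: getattr(self, k) for k in keys}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

from . import inference as _inf
from .types import DesignBundle, ParameterSet

__all__ = ["MixedPoissonMCMC", "MixedPoissonLaplace"]


class MixedPoissonMCMC(BaseEstimator):
    """Bayesian fit of the bivariate three-level Poisson mixed model.

    Parameters mirror :class:`~geopoisson.inference.PriorSpec` and
    :class:`~geopoisson.inference.ChainConfig`.  After ``fit``:

    ``samples_``
        dict of per-chain draw arrays.
    ``summary_``
        :class:`~geopoisson.inference.PosteriorSummary`.
    ``params_``
        posterior-mean :class:`~geopoisson.types.ParameterSet`.
    ``random_effects_``
        posterior-mean empirical-Bayes effects.
    """

    def __init__(self, b_sd=10.0, iw_df=3.0, iw_scale=0.1,
                 n_iter=25_000, n_burnin=5_000, thin=2, n_chains=2,
                 seed=0, likelihood_power=1.0, rhat_threshold=1.05):
        self.b_sd = b_sd
        self.iw_df = iw_df
        self.iw_scale = iw_scale
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.n_chains = n_chains
        self.seed = seed
        self.likelihood_power = likelihood_power
        self.rhat_threshold = rhat_threshold

    def fit(self, X: DesignBundle, y=None):
        priors = _inf.PriorSpec(b_sd=self.b_sd, iw_df=self.iw_df,
                                iw_scale=self.iw_scale)
        cfg = _inf.ChainConfig(
            n_iter=self.n_iter, n_burnin=self.n_burnin, thin=self.thin,
            n_chains=self.n_chains, seed=self.seed,
            likelihood_power=self.likelihood_power,
            rhat_threshold=self.rhat_threshold,
        )
        self.samples_, self.summary_ = _inf.fit_mcmc(X, priors, cfg)
        fe = self.summary_.fixed_effects
        re = self.summary_.random_effect_summary
        d = X.n_diseases
        sig = {}
        for level in ("state", "county"):
            rows = re[re["level"] == level]
            S = np.empty((d, d))
            diseases = list(X.spec.diseases)
            for _, r in rows.iterrows():
                i, j = (diseases.index(s) for s in r["pair"].split(":"))
                S[i, j] = S[j, i] = r["estimate"]
            sig[level] = S
        self.params_ = ParameterSet(
            b=pd.Series(fe["estimate"].to_numpy(), index=fe["parameter"]),
            sigma_state=sig["state"], sigma_county=sig["county"],
        )
        self.random_effects_ = self.summary_.eb
        self.converged_ = self.summary_.converged
        self.n_features_in_ = X.X.shape[1]
        return self

    def predict(self, X: DesignBundle):
        """Posterior-mean expected counts N * exp(eta) for a design."""
        from .model import linear_predictor
        eta = linear_predictor(X, self.params_, self.random_effects_)
        return X.N * np.exp(eta)


class MixedPoissonLaplace(BaseEstimator):
    """Maximum marginal-likelihood fit via the Laplace approximation.

    After ``fit``: ``params_`` (point estimates), ``se_`` (Wald standard
    errors), ``loglik_``, ``converged_``, ``random_effects_`` (empirical-
    Bayes modes at the estimates).
    """

    def __init__(self, start="auto", max_iter=300, compute_se=True, gtol=1e-6):
        self.start = start
        self.max_iter = max_iter
        self.compute_se = compute_se
        self.gtol = gtol

    def fit(self, X: DesignBundle, y=None):
        res = _inf.fit_laplace(X, start=self.start, max_iter=self.max_iter,
                               compute_se=self.compute_se, gtol=self.gtol)
        self.params_ = res.params
        self.se_ = res.se
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.random_effects_ = _inf.empirical_bayes(X, res.params)
        self.n_features_in_ = X.X.shape[1]
        return self

    def predict(self, X: DesignBundle):
        from .model import linear_predictor
        eta = linear_predictor(X, self.params_, self.random_effects_)
        return X.N * np.exp(eta)
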