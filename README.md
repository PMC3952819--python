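# geopoisson

Bivariate three-level mixed-effects Poisson modelling of county-level
neurodevelopmental disorder incidence.

Epidemiologists mapping rare-disorder incidence from administrative claims
face a common structure: disease counts for two related phenotypes — here
autism spectrum disorders (ASD) and intellectual disability (ID) —
tabulated by gender across ~3,000 counties nested in ~51 states, with
county-level covariates (ethnic composition, income, urbanization,
insurance coverage, population-normalised congenital-malformation and
viral-infection rates) and hand-coded state special-education policy
variables. `geopoisson` implements the full analysis for that structure:
a correlated-random-effects Poisson regression, Bayesian (MCMC) and
Laplace maximum-likelihood estimation, empirical-Bayes disease mapping, a
descriptive layer, and a synthetic-data generator that reproduces the
statistical skeleton of such claims panels so every stage is testable
without access to proprietary data.

## The model

Counts are Poisson with a population offset and a log-linear rate,

```
y_ijkl ~ Poisson(N_ijkl · λ_ijkl),      log λ_ijkl = x'_ijl b_k + v_ik + v_ijk
```

for state *i*, county *ij*, disease *k* ∈ {ASD, ID} and gender *l*.  Each
disease has its own block of 22 mean-centered fixed-effect weights
(intercept, gender, socioeconomic and ethnic covariates, environmental
indicator rates, and the policy codes CFR/DSM/ASD-criteria plus a
three-indicator contrast of the four-level Eval code), 44 weights in all.
The zero-mean random effects are independent across levels but correlated
across the two phenotypes within a level:

```
(v_i1, v_i2)  ~ N(0, Σ_state),      (v_ij1, v_ij2) ~ N(0, Σ_county),
```

adding 6 free covariance parameters for a 50-parameter model.  Effects are
reported as event rate ratios `exp(b)` with 95% interval endpoints
transformed the same way, and cross-phenotype association as the
correlations implied by Σ at each level.

Estimation routes:

* **MCMC** (`MixedPoissonMCMC` / `fit_mcmc`) — Metropolis-within-Gibbs with
  conditional-mode proposals for the weight blocks, vectorised bivariate
  random walks for the effects, conjugate inverse-Wishart covariance
  updates, and translation moves along the likelihood-flat
  covariate-vs-effect ridges.  Convergence is monitored with split-R̂.
* **Laplace ML** (`MixedPoissonLaplace` / `fit_laplace`) — quasi-Newton
  maximisation of the Laplace-approximated marginal likelihood with Wald
  standard errors; an adaptive Gauss–Hermite marginal is available as a
  cross-check (`marginal_loglik(..., method="adaptive_quadrature")`).
* **Empirical Bayes** (`empirical_bayes`) — per-state joint posterior modes
  of the random effects, keyed by state/county id for mapping.

## Worked example

```python
import geopoisson as gp
from geopoisson import ChainConfig, PriorSpec, fit_mcmc

geo = gp.generate_geography(n_states=10, counties_per_state=20, seed=7)
covars = gp.generate_covariates(geo, seed=7)
panel, effects = gp.simulate_panel(geo, covars, seed=7)   # known truth
design = gp.build_design(panel, covars, geo)              # 800 x 44

samples, summary = fit_mcmc(design, PriorSpec(),
                            ChainConfig(n_iter=8000, n_burnin=2000,
                                        thin=2, n_chains=2, seed=7))
fe = summary.fixed_effects.set_index("parameter")
print(fe.loc["ASD:ConGenM", ["estimate", "rate", "rate_ci_lower",
                             "rate_ci_upper", "p_value"]])
```

prints (to three decimals)

```
ASD:ConGenM: estimate +1.134  rate 3.108 [1.758, 5.499]  p 0.00033
ASD:Gender:  estimate -0.673  rate 0.510 [0.493, 0.529]  p 0.00033
ASD:Viral_M: estimate +0.069  rate 1.072 [0.945, 1.214]  p 0.275
county-level ASD:ID correlation: 0.925 (posterior sd 0.020)
converged: True   max R-hat: 1.019
```

The generator's default true weight for the male genital-malformation
covariate is 1.345 (rate ratio 3.84), so on this 200-county panel the
posterior rate ratio 3.11 with interval [1.76, 5.50] recovers the signal;
the gender rate ratio 0.51 says female incidence is about half the male
rate at equal covariates; Viral_M's interval straddles 1 — 200 counties are
too few to pin a 20% effect.  The county-level cross-phenotype correlation
posterior (0.925 ± 0.020) reflects the generating correlation 0.962.
p-values are two-sided posterior tail fractions floored at 2/draws.

The same pipeline runs from a shell:

```
geopoisson run --desk-scale --seed 7 --out-dir out/
geopoisson simulate --paper-scale --seed 1 --out-dir big/   # 3,111 counties
```

writing CSV tables (panel, covariates, coefficient summary table, empirical-
Bayes effects keyed by state/county id, rate summaries, decile profiles,
comorbidity odds ratio) plus a manifest with seeds and checksums.

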