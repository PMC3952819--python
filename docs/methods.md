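# Methods

## Model

The observed count for state *i*, county *ij*, disease *k* and gender *l*
is `y_ijkl ~ Poisson(N_ijkl λ_ijkl)` with
`log λ_ijkl = x'_ijl b_k + v_ik + v_ijk`.  `N_ijkl` is the gender-specific
county population (offset).  The fixed-effect design is block-diagonal over
the two diseases: every covariate has a separate weight per disease.  The
random effects are exchangeable within a level, independent across levels,
and bivariate-normal across the two diseases within a level, with
covariance matrices `Σ_state` and `Σ_county` (three free parameters each).
With the default covariate list — intercept, gender, Income, Poor, Urban,
Insured, seven ethnic proportions, ConGenM, CongMrepM, Viral_M, the ±1
policy codes CFR/DSM/ASDcrit and three Eval indicator contrasts — the model
has 22 weights per disease, 44 + 6 = 50 free parameters.

Design conventions (configurable through `ModelSpec`):

* gender indicator 0 = male (reference), 1 = female, so `exp(b_Gender)` is
  the female:male rate ratio;
* the four-level Eval policy code enters as indicators for levels 1, 2 and
  −1 against reference level −2;
* all non-intercept columns are mean-centered, unweighted over the design
  rows of their disease block (equivalently over counties, since the panel
  is balanced); intercepts therefore refer to a covariate-average county;
* Income is in thousands of dollars, all rate covariates in percent;
* rows with a zero population offset are dropped with a warning rather
  than given −∞ linear predictors;
* the female-specific environmental covariates (ConGenF, CongMrepF,
  Viral_F) and the pregnancy covariates (ect_pr, abnormal_concept,
  spont_abort, mult_gest) are generated and supported but excluded from the
  default fixed-effect list.

`log(y!)` is evaluated through the log-gamma function and all likelihood
constants are retained, so values are directly comparable across methods
and against external implementations.

## Marginal likelihood

Random effects are integrated out per state block (the state's pair of
effects plus its counties' pairs).  Two approximations are provided:

* **Laplace** — Newton ascent to the block's joint mode (dense solve; the
  blocks are at most a few hundred dimensions at desk scale) and a Gaussian
  correction from the log-determinant of the negated Hessian.  Newton uses
  a scale-free decrement stopping rule, because absolute gradient
  tolerances become meaningless when the prior precision grows as
  variances approach zero.
* **Adaptive Gauss–Hermite** — a nested rule: an outer adapted grid over
  the state pair (centered at the profiled Laplace mode, scaled by the
  Schur-complement Hessian), and for each outer node an inner adapted grid
  per county.  `n_quad` points per dimension (default 15).

Accuracy is count-dependent: on single-cell instances the quadrature
marginal tracks a fine-grid trapezoid oracle to ~1e-10 regardless of
counts, while the Laplace value is accurate to ~1e-4 at cells of ~100
events and to better than 1e-6 only at very large cells (~10^6 events,
small variances).  The two methods agree to 1e-3 on desk-scale instances
when cells carry on the order of a thousand events; at sparse-count cells
Laplace should be treated as ~1e-2-accurate and the quadrature route used
for high-precision comparisons.

## Bayesian estimation

Priors: independent N(0, 10²) on each weight; inverse-Wishart(df = 3,
scale = I) on each covariance matrix.  The scale was chosen so the implied
variance prior is diffuse across the range log-rate variance components
occupy in disease-mapping panels (roughly 0.1–10); a much smaller scale
visibly shrinks the level-3 variance when only ~10 states inform it and
favours a degenerate mode in which the handful of state-policy contrasts
absorbs the state effects.

The sampler is Metropolis-within-Gibbs:

* each disease's weight block is updated by an independence
  Metropolis–Hastings step proposing from the Gaussian (Newton) approximation
  of its full conditional given the effects, plus a preconditioned
  random-walk companion step (the independence step alone can stall when
  the chain sits in a skewed tail of a weakly identified coordinate);
* county and state effect pairs are updated with vectorised bivariate
  random walks shaped by the current level covariance (the conditional
  geometry is extremely anisotropic when the cross-disease correlation is
  near one);
* covariances get conjugate inverse-Wishart draws given the effects;
* *translation moves* resample the exact likelihood-flat ridges: shifting a
  state-constant (or county-constant) column's weight by δ while
  subtracting δ·x from the paired effects leaves every linear predictor
  unchanged, so acceptance is decided by the priors alone.  Single-disease
  moves, joint two-disease moves (proposals shaped by the current level
  covariance), an intercept-vs-state-effects move and a
  state-vs-its-counties move are all included; without them the policy
  contrasts and intercepts mix hopelessly slowly when ~10 level-3 units
  carry the information.

Initialisation: weights from a ridge IRLS fit in which state-constant
columns (other than the intercepts) are strongly penalised, so level-3
variation starts in the state effects rather than in the policy contrasts;
effects from crude per-unit residual log-rates; covariances from the
empirical covariance of those initial effects.  Starting all effects at
zero is a funnel trap — the first conjugate draw collapses the covariance.
Proposal scales adapt by Robbins–Monro during burn-in only, preserving
detailed balance afterwards.

Summaries follow the conventional reporting layout: posterior means,
equal-tailed 95% intervals, rate columns obtained by exponentiating the
estimate columns (the rate interval is `exp` of the estimate interval
endpoints — never the mean of per-draw exponentials), and two-sided
posterior tail p-values floored at 2/draws and displayed as "< floor" when
a tail is empty.  Split-R̂ (via arviz) below 1.05 on all parameters marks a
run converged; otherwise summaries carry a warning flag.  Setting
`likelihood_power = 0` removes the data term — a validation hook under
which the stationary law of each covariance is exactly its inverse-Wishart
prior (checked by a Kolmogorov–Smirnov test against the inverse-gamma
marginal of a diagonal entry).

## Laplace maximum likelihood

`fit_laplace` maximises the Laplace marginal over (b, log-Cholesky factors
of the covariances) with L-BFGS-B.  Coordinates are preconditioned by the
fixed-effects GLM standard errors — raw curvatures span six orders of
magnitude and unscaled quasi-Newton stalls far from the optimum — and
finite-difference steps are 1e-4 in the scaled space, matched to the
objective's noise floor.  Standard errors come from a central
finite-difference Hessian in the scaled space (delta method back to the
covariance scale).  `fix_sigma` pins both covariance matrices, which gives
the exact zero-variance limit: the fit then reproduces a plain Poisson GLM
(verified against an IRLS oracle to ~1e-7 relative).  ML point estimates
and posterior means agree on the joint-SE scale on average; for
hyper-identified coordinates (joint SE of a few thousandths) the O(SE²)
difference between a prior-free maximum and a posterior mean can reach one
to two joint SEs while being negligible in absolute terms.

## Empirical Bayes

`empirical_bayes` returns the per-state joint posterior mode of the
effects at fixed parameters (the same inner problem the Laplace marginal
solves); the MCMC path reports posterior means of the sampled effects.
Units with no data shrink exactly to zero; county effects average
approximately to zero within each state on balanced data.

## Synthetic data

The generator emulates the structure of a claims-derived county panel:

* **Geography** — configurable states × counties (presets: 51 × 61 = 3,111
  "paper scale"; 10 × 20 "desk scale"); gender populations i.i.d.
  log-normal (median 10,000, log-sd 1.3) for a heavy right tail like US
  county sizes.
* **Covariates** — ethnic proportions from a scaled Dirichlet with a
  remainder category (sums never exceed 100%), socioeconomic shares from
  beta distributions, environmental indicator rates from right-skewed
  gammas truncated to [0, 100] by rejection.  Dispersions are set to
  census-like values; the male genital-malformation rate averages ~0.27%
  with 3,111-county maxima around 2.4%.  These distributions are fixtures:
  the source data's covariate distributions were never published.
* **Policy codes** — i.i.d. per state from configurable frequencies; real
  state codings are not public, so the assignment is a fixture.
* **True parameters** — the default weight and covariance magnitudes are
  the published point estimates (e.g. ConGenM weight 1.345 for ASD;
  state-level covariance 2.666 with correlation 0.974; county-level
  correlation 0.962), so recovery experiments run at realistic magnitudes.
  The default intercepts are set from the published descriptive rates
  (median ASD male county rate ~0.023%) rather than from the printed
  intercept rows, which are not on a per-person rate scale consistent with
  those descriptives.
* **Counts** — `y ~ Poisson(N exp(η))` through the same design code the
  fitters use; the realised effects are returned for recovery testing.
  Random-effect configurations implying a cell rate above `max_rate`
  (default 50% — far beyond any observed claims rate) are rejected and
  redrawn with a logged count; under the defaults this truncates only a
  remote tail of the Gaussian law (it binds mainly when compound extremes
  of state effect, county effect and covariates coincide).  Counts are
  finally clipped at N so the panel invariant y ≤ N holds identically.
* **Patients** — per (county, gender) stratum, flags for ASD/ID and
  congenital malformation with marginals equal to the panel's observed
  rates and a 2×2 joint solving the Plackett equation for a target odds
  ratio (default 5.53); infeasible targets raise with the attainable
  range.  Degenerate (zero-prevalence) strata produce no flagged patients.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring counties, non-random insurance coverage, correlation between
covariates, or reporting artifacts.  Passing recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to the ways real claims data violate them.

## Descriptives

County rates are exact y/N proportions with unweighted county-level
summaries (mean/median/max per disease × gender).  Cross-phenotype
correlation is the Pearson product-moment coefficient with a two-sided
t-test.  Decile profiles rank counties by a predictor (stable county-id
tie-break), split into ten equal-count bins, and average the outcome rate
per bin; the profile is invariant to order-preserving predictor
transforms.  The comorbidity odds ratio is the 2×2 cross-product with
Fisher's exact two-sided p; the default interval is the log-OR normal
approximation, with the conditional-ML exact interval available by flag;
zero cells fall back to a 0.5 continuity correction with an explicit note.

## Problem sizes and numerical choices

The recovery harness runs 20 signal replicates at 10 states × 300 counties
(published-magnitude truth, single chains of 3,000 iterations with 1,000
burn-in) and 15 null replicates (all non-intercept weights zero, variances
0.01) with shorter chains — sizes chosen to keep full-suite runs in the
single-digit minutes while leaving Monte Carlo error far below the
3-posterior-SD recovery band.  Null coverage is asserted at ≥ 0.90 against
a nominal 0.95 because weakly identified policy contrasts (their CI is
essentially the prior) can only over-cover; the informative direction of
failure is under-coverage.  Default production chains are 2 × 25,000
iterations with 5,000 burn-in and thinning 2.

Degenerate inputs: singular covariance matrices are rejected wherever a
density or precision is required; simulation accepts positive
semi-definite matrices (eigendecomposition factor).  Zero-population cells
never produce counts.  All generators and both fitters are deterministic
for a fixed seed; per-stage RNG streams are spawned from the master seed so
regenerating one stage does not perturb the others.

## Known limitations

* The likelihood engine is specific to this design: Poisson log link, two
  nested random-effect levels, shared covariance across units within a
  level.  It is not a general GLMM engine.
* Laplace accuracy degrades at sparse counts (see above); for cells with a
  handful of events the MCMC route is the reference.
* With ~10 level-3 units the policy contrasts and the state-effect
  variance are only weakly separated; the posterior can harbour a
  secondary mode in which policy columns absorb state variation.  The
  default priors and initialisation target the scientifically meaningful
  mode, but single-chain fits on unusually aligned data sets can still
  land in the degenerate one.
* The comorbidity generator couples ID to malformation independently of
  ASD given the margins; three-way dependence is not modelled.
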