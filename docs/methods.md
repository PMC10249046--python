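# Methods

## Model

`stagessm` implements a state-space model for a population whose cohorts
pass sequentially through `n` life stages (default `n = 4`, indexed
1..n, with stage n the reproducing adults).  Cohorts do not overlap:
adults reproduce and die, so the recursion can be initialised at the adult
abundance `N_{n,0}` (a fixed-effect parameter, stored as `log_N_init`).

Process model, for cohorts `t = 1..T`:

    N_{1,t} = rho_t * N_{n,t-1}
    N_{i,t} = phi_{i-1,t} * N_{i-1,t},            1 < i <= n
    log rho_t     ~ Normal(w_{R,t} beta_R,  sigma_pR^2)
    logit phi_{i,t} ~ Normal(w_{i,t} beta_Si, sigma_pSi^2)

Each design matrix carries an intercept column plus covariates; the
process SDs represent genuine environmental stochasticity around the
covariate-driven means.

Observation model: each stage is monitored by one survey whose index is
proportional to abundance up to a multiplicative bias (catchability)
`psi`, with known log-scale sampling SD `sigma_o`:

    log Y_{i,t} ~ Normal(log(psi_i N_{i,t}) - sigma_o^2/2, sigma_o^2)

The `-sigma_o^2/2` shift makes the index unbiased on the natural scale:
`E[Y_{i,t}] = psi_i N_{i,t}`.  Two stages may share a survey label, in
which case they share one `psi`.  An optional index `Y_init` of `N_{n,0}`
uses the adult survey's bias parameter.  Missing observations contribute
exactly nothing to the likelihood.

### Identifiability

`N_{n,0}` and the biases enter the likelihood only through the products
`N_{n,0} psi_i`: the map `(log N0, psi) -> (log N0 + log c, psi / c)`
leaves the joint density exactly invariant (`rescale`, verified to 1e-10
in the tests).  A fit therefore requires at least one `psi` (or
`log_N_init`) to be fixed, and covariate-driven vital rates.  When the
reference bias `psi_j` is fixed at a wrong value `psi_ref`, estimates
converge to the *adjusted true values* `N0 psi_j / psi_ref` and
`psi_i psi_ref / psi_j`; ratios of estimated biases still track ratios of
the true biases, and the state-process parameters are unaffected.  Even
when identifiable, the model is *near*-redundant: intercepts and biases
sit on long likelihood ridges, which drives most of the numerical choices
below.

## Laplace maximum likelihood

The marginal likelihood of theta integrates over the latent vital rates
`u = (log rho, logit phi)`.  Because log-abundance is `log N0` plus a
cumulative sum of log vital rates, the joint negative log-likelihood is
smooth in `u`, and the integral is approximated by Laplace:

    -log L(theta) ~ f(theta, u_hat) + 1/2 log det H - dim(u)/2 log 2 pi

* Latent variables are kept on log/logit scales with plain normal process
  densities (no Jacobians), the standard parameterisation for
  Laplace-approximated random-effects models.
* The inner optimiser is Newton with analytic gradient and Hessian; the
  exact Hessian's residual-curvature term can be indefinite far from the
  mode, so steps fall back to the always-positive-definite Gauss-Newton
  matrix (process precision + J'WJ) when needed.  Inner tolerance: max
  |gradient| <= 1e-8 at reported optima; 1e-5 suffices during the outer
  search (the Laplace value error is quadratic in the residual gradient).
* The outer gradient is computed analytically by implicit differentiation
  (the log-det derivative needs only the third derivative of log-expit,
  which is diagonal); it is validated against central finite differences
  in the tests.  Optimisation uses L-BFGS-B on unconstrained scales
  (log sigma, log psi, log N0, beta as-is) with box bounds
  (|beta| <= 10, sigma_p in [1e-3, 10], |log psi| <= 12) that keep the
  search off degenerate plateaus, plus up to three restarts because line
  searches can stall on the bias/intercept ridges.
* Starting values are data-driven: crude abundances `Y/psi_start`, least
  squares of implied log-recruitment and logit-survival on the
  covariates, and residual SDs floored at 0.15.  Implied survival ratios
  above 1 signal a misjudged bias start: when the offending stage's bias
  is free its start is rescaled to make the ratios feasible (with a
  second, joint rescaling of all free biases when the clash is against a
  fixed reference), and any remainder is shrunk into (0,1) rather than
  clipped — clipping saturates the logit and creates a degenerate
  starting basin.
* The covariance of the free parameters is a finite-difference Hessian of
  the analytic gradient at the optimum (central by default; forward in
  the large replicate studies).  Positive-definiteness is judged with a
  relative eigenvalue noise floor (1e-6 of the largest eigenvalue),
  because flat, bound-saturated directions otherwise produce
  noise-level negative eigenvalues.  A non-positive-definite Hessian does
  not overwrite estimates; it sets `hessian_pd=False` and downstream code
  decides (the simulation study resimulates, mirroring common practice).

AICc uses `n_obs` = number of non-missing index observations including
`Y_init`.  Profile likelihoods re-optimise all remaining free parameters
at each grid value, visiting points outward from the MLE with warm
starts.  One-step-ahead residuals use a Gaussian filtering approximation:
log-observations are treated as jointly Gaussian (log-survival linearised
about its process mean), and standardised innovations are obtained by
sequential conditioning (forward substitution with the Cholesky factor)
in cohort-then-stage order.

## Bayesian inference

Priors: `log N_{n,0} ~ Uniform(9, 15)`; recruitment coefficients
`Normal(0, tau = 1)`; survival coefficients `Normal(0, tau = 3(m+1)/pi^2)`
with `m` covariates (0.61 at `m = 1`); process SDs and free biases
`Exp(1)`.  Precisions, not variances, parameterise the normals.

The sampler is Metropolis-within-Gibbs over `(theta, u)` with kernels
chosen for the model's geometry:

* exact conjugate Gibbs draws for the regression coefficients, the latent
  log-recruitment vector (the observation model is linear in it) and
  `log N0` (truncated normal);
* per-cohort random-walk blocks for logit-survival, and random walks on
  `log sigma` and `log psi`, with proposal scales adapted during burn-in
  only (the post-burn-in kernel is fixed and valid);
* interweaved non-centered `sigma` updates that rescale the latent row
  together with the SD — without these the sampler gets trapped in the
  funnel when a process SD drifts toward zero;
* a Haario-style adaptive joint block over the confounded subvector
  (free `log psi`, intercepts, `log N0`);
* every 4th iteration, a *Laplace-transport* move: a joint theta proposal
  (adaptive covariance over all free parameters) in which the latent
  field is mapped deterministically through the whitening transforms of
  the old and new Laplace conditionals.  The acceptance ratio uses the
  exact joint posterior plus the transport Jacobian, so the kernel
  remains exact; for a Gaussian conditional the ratio collapses to the
  marginal-likelihood ratio, which is what lets theta cross the
  bias/intercept ridge at any latent dimension.  (The transport map relies
  on the latent modes solved to gradient tolerance 1e-5; the residual
  irreversibility this leaves is far below the posterior scales, and the
  posterior means are indistinguishable from the MLEs in the
  well-identified scenarios, as the tests check.)

Chains are initialised at a jittered Laplace mode: purely data-driven
starts can land in a secondary basin of the ridged posterior that
random-walk moves escape only very slowly.  The default run is 4 chains
of 20,000 iterations with the first half discarded — a deliberate
scaled-down choice relative to overnight-scale analyses (the reference
configuration of 10 chains of 150,000 is available by argument).
Convergence is summarised by the classic split-chain Gelman-Rubin
statistic (cross-checked against `arviz`'s split method in the tests),
with max R-hat < 1.1 as the working threshold.

## Synthetic data

The generator reproduces the structure of the two study conditions:

| quantity | low information | high information |
|---|---|---|
| log N_{4,0} | 13.82 | 13.82 |
| beta_R | (1.00, -0.50) | (1.75, -1.00) |
| beta_Si | (1.00, 1.30) | (1.00, 2.00) |
| sigma_p (all rates) | 0.50 | 0.25 |
| sigma_o (all surveys) | 0.10 | 0.05 |
| psi (biased) | (0.20, 0.10, 0.40, 0.50) | same |

Defaults are `n = 4` stages, `T = 20` cohorts, one survey per stage, one
covariate per vital rate drawn i.i.d. standard normal (the slopes above
are meaningful on that scale), distinct covariates across rates, constant
`sigma_o` over time, and an observed `Y_init`.  Everything is driven by a
single seed through spawned substreams.

What the generator does *not* emulate: real covariate series with
autocorrelation or cross-correlation, time-varying observation SDs,
overlapping cohorts, density dependence, or covariate-dependent
catchability.  Passing tests therefore demonstrate correct behaviour of
the estimators under the model's own assumptions, not robustness to the
further misspecifications real monitoring data can carry.

## Simulation experiments

`run_bias_study` crosses biased/unbiased data with the two model types
(all `psi` fixed at 1; `psi_4` fixed at 1 and the rest estimated) on the
low-information condition, scores natural-scale MLEs against (adjusted)
truths by relative bias `(est - true)/|true|`, MSE and sampling SD, and —
following the replicate protocol — replaces a converged fit whose Hessian
is not positive definite with a fit to a freshly simulated dataset, up to
10 attempts per slot (a cap avoids livelock; exhausted slots are counted
and excluded).  Relative bias uses `|true|` in the denominator because
slope truths can be negative; scored adjusted truths are positive, where
the two conventions coincide.  Replicate fits use a speed-tuned optimiser
profile (capped iterations, forward-difference covariance, coarser
restart tolerance); the residual optimiser error this admits is far below
replicate Monte-Carlo noise, which the acceptance margins confirm.

The expected qualitative outcomes, all asserted in the acceptance tests
at 200 replicates (100 for the ratio check): the matched pairing recovers
coefficients with |mean relative error| < 0.1; ignoring true bias drives
survival intercepts toward saturation and inflates process-SD estimates;
estimating unnecessary biases inflates intercept sampling SDs
(bias-variance tradeoff); and estimated-bias ratios track true ratios
within 15% under a misfixed reference.

`vital_rate_curves` sweeps one covariate per rate (others at their mean)
and summarises 10,000 simulated rate realisations by mean and 2.5/97.5
percentiles — process stochasticity only.  `intercept_grid_scan` fixes
triplets of intercepts on a grid (10 points per dimension by default),
re-optimises everything else, retains points not rejected by a
likelihood-ratio test (chi-square df = 3, the number of fixed
parameters, at alpha = 0.05) and emits curves per retained point; grid
bounds default to MLE +- 2 SE but externally motivated limits (fecundity
caps, survival floors) are caller-supplied configuration.

## Numerical edge cases and limitations

* Fits to biased data with all biases fixed at 1 genuinely push survival
  intercepts toward +infinity (an index ratio above 1 cannot be explained
  with survival < 1); estimates then sit at the box bound with a flat
  profile, and Hessian positive-definiteness becomes the practical
  convergence filter.
* Process-SD estimates in the matched pairing are biased low at T = 20
  (maximum likelihood has no REML-style correction here); this is visible
  in the study output and is a property of the estimator, not a bug.
* The profile-based 95% interval convention is the chi-square 1-df
  1.92-drop rule; profiles on ridge parameters can be far from quadratic
  and then deliberately disagree with Wald intervals.
* The Gaussian OSA-residual approximation linearises log-survival about
  the process mean; with extreme survival probabilities or very large
  process SDs its calibration degrades.
* `sigma_o` is treated as known throughout; estimating it alongside the
  process SDs is a known confounding axis and out of scope.
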