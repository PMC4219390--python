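# Methods

## Model

The package couples two submodels through shared random effects.

**Longitudinal.**  For subject *i* at time *t*,
`Y_ij = W_i(t_ij) + e_ij` with `e_ij ~ N(0, sigma_e^2)` independent across
occasions, and

`W_i(t) = x_i'(t) beta + z_i'(t) b_i + u_i' delta`,  `b_i ~ MVN(0, Sigma)`.

The fixed design holds an intercept, baseline covariates as main effects,
and a function of time — raw linear, or a restricted cubic spline of time.
The random design holds an intercept and optionally a linear (or spline)
time term.  `sigma_e` is interpreted as classical measurement-error SD;
serial correlation and heteroscedastic error are out of scope.

**Survival.**  Right-censored proportional hazards with a parametric
baseline: Weibull (`H0(t) = lambda t^gamma`) or flexible parametric
(restricted cubic spline for `log H0` as a function of `log t`; one spline
degree of freedom is exactly Weibull).  The log-likelihood is
`sum_i d_i log h_i(T_i) - H_i(T_i)`; delayed entry and unspecified (Cox)
baselines are not supported — the latter is known to understate standard
errors in joint models.

**Association.**  The primary structure is the *intercept* association
`h_i(t) = h0(t) exp(alpha (beta_0 + b_0i) + phi'v_i)`: the hazard depends on
the subject's true baseline biomarker level, which is the quantity of
prognostic interest and makes `H_i(t)` available in closed form.  A
*current-value* structure `alpha W_i(t)` is provided as a secondary option;
its cumulative hazard needs an inner numerical integral.

## Likelihood evaluation

The subject contribution integrates the product of the longitudinal
Gaussian density, the survival factor and the random-effects prior over
`b_i`.  Because the longitudinal factor is Gaussian and linear in `b_i`, it
is integrated analytically, leaving

`L_i = f_marg(Y_i) * E[ h_i(T_i)^{d_i} exp(-H_i(T_i)) | Y_i ]`,

where `f_marg` is the closed-form marginal density
`N(X_i beta, Z_i Sigma Z_i' + sigma_e^2 I)` and the expectation runs over
the subject's empirical-Bayes Gaussian posterior of `b_i`.  That remaining
expectation is evaluated by Gauss–Hermite quadrature with nodes centred and
scaled at the posterior — adaptive quadrature by construction, without a
per-iteration mode search.  For the intercept association only the `b_0`
marginal matters, so the integral is one-dimensional regardless of the
random-effects dimension; for the current-value association a tensor
product of nodes over the posterior is used.  This factorisation is exact
in the longitudinal direction and reduces *identically* to
(mixed-model marginal log-likelihood + survival log-likelihood) when
`alpha = 0`, a property the test suite asserts.  On the simulation designs
the quadrature is converged to well below 1e-4 per subject at the default
9 nodes; a non-adaptive mode (nodes on the prior) is retained for
cross-checks.

The current-value inner integral uses 15-point Gauss–Legendre after the
substitution `t = T u^2`: the Weibull integrand `t^{gamma-1}` has a
square-root kink at zero that plain Gauss–Legendre resolves poorly, while
after substitution the `gamma = 1.5` baseline is polynomial and integrated
exactly.

## Estimation

Parameters are transformed to an unconstrained scale: `log sigma_e`,
log-Cholesky factor of `Sigma`, `log lambda`, `log gamma`.  Survival
covariates are centred and scaled internally (the centring shift is
absorbed exactly by the baseline-hazard intercept) — without this the
observed-information matrix for covariates like age (scale ~65) is so
ill-conditioned that quasi-Newton steps stall.  Optimisation is two-phase
L-BFGS-B (loose then tight tolerances) with numeric gradients, started from
a two-stage fit: the mixed model alone, then a survival fit with the
empirical-Bayes intercepts as a covariate.  One perturbed restart is
attempted on failure; a fit that still fails is returned with
`converged_ = False`, never silently.  The variance matrix is the inverse
observed information from central-difference second derivatives
(implemented in-package), mapped back to the natural covariate scale;
Wald 95% intervals follow.  Spline bases are the Royston–Parmar restricted
cubic splines with boundary knots at the data extremes and interior knots
at equally spaced linear-interpolation centiles (survival knots on the log
event times); columns are scaled by the squared boundary span but not
orthogonalised, so coefficients are parameterisation-dependent but
directly interpretable.

## Synthetic data

The simulator generates the evaluation design used throughout: 300
subjects; random intercept SD 1 and slope SD 0.25 with correlation 0.25;
`beta_0 = beta_1 = 0`; annual visits at 0–4 years with measurement-error SD
in {0.1, 0.5, 1}; Weibull baseline `lambda = 0.1`, `gamma = 1.5`; a
Bernoulli(0.5) treatment with log HR −0.5 and a N(65, 12²) age with log HR
0.01; association `alpha` in {−0.5, −0.25, 0.25, 0.5}; administrative
censoring at 5 years (≈18.9% survive at the covariate means).  Event times
come from analytic inversion of the Weibull cumulative hazard;
measurements scheduled at or after the observed time are discarded (the
only coherent choice under the joint likelihood), with the baseline visit
always retained.  All draws come from one seeded generator in fixed order,
so a dataset is reproducible from `(scenario, seed)` alone.

What the generator does *not* emulate: nonlinear trajectories, covariate
effects on the biomarker, informative censoring or visit schedules, and
non-Gaussian error.  Passing tests therefore demonstrate correctness of
the estimator under the stated design, not robustness to those features of
real registry data.

## Simulation study and problem sizes

`run_scenario` fits both estimators to each replicate and summarises bias,
percentage bias (`100*bias/alpha`, so attenuation gives negative values for
either sign of `alpha`), MSE and 95%-CI coverage over converged replicates,
with Monte-Carlo SEs (`sd/sqrt(R)` for bias, binomial for coverage)
attached.  The package's own evaluation runs 200 replicates per scenario
(the original design used 1000), a size chosen so the whole study re-runs
in minutes on a single core while keeping Monte-Carlo SEs on bias near
0.004–0.005; the replicate files are persisted for exact re-summarisation.

## Prediction

For a new patient with a single baseline value `Y_0`, the random-intercept
posterior is the conjugate Gaussian with the classic shrinkage mean
`k (Y_0 - fixed part)`, `k = sigma_b^2 / (sigma_b^2 + sigma_e^2)` —
longitudinal information only, since the patient's event time is unknown
at prediction time.  Survival is reported both as a plug-in curve at the
posterior mean and as the marginal curve `E[exp(-H(t|b_0))]` by
Gauss–Hermite over the posterior; the marginal curve is the recommended
default because propagating baseline measurement uncertainty is the point
of the method.  One caveat worth knowing: with a single Gaussian baseline
the naive model's attenuated coefficient and the joint model's shrunken
plug-in predictor nearly coincide, so the *plug-in* curve shows the
expected correction direction at high observed baselines, while the
marginal curve can sit above the naive curve deep in the tail (Jensen's
inequality applied to averaging `exp(-H)` over the posterior).

## Defaults that matter

| parameter | default | why |
|---|---|---|
| `nodes` | 9 (odd, one node at the mode) | converged to <1e-4/subject on the study designs |
| `adaptive` | True | posterior-centred nodes; prior-grid fallback for checks |
| `gl_nodes` | 15 | inner integral, current-value association only |
| `family` | `weibull` | generating family of the evaluation design |
| `df` (fpm) | 2 | the df selected by AIC/BIC in typical registry fits |
| optimiser tolerances | ftol 1e-8 then 1e-12 | loose-then-tight two-phase refinement |
| Hessian step | 1e-4 relative | central differences, stable for these likelihoods |

## Known limitations

Only intercept and current-value associations (no slope or variability
structures); single biomarker; no left truncation or dynamic (post-baseline)
risk updating; Gaussian response only; the fpm fit permits locally
non-monotone cumulative hazards during optimisation and flags them
(`monotone_`) rather than constraining them.
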