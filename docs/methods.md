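# Methods

This note documents the statistical machinery in `crtmi`: the data-generating
model, the two analyzers, the missing-data strategies, the pooling rules, the
scenario metrics, and the numerical and design choices behind them.

## Data-generating model

One simulated trial is a balanced, completely randomized, two-arm CRT with k
clusters per arm and m subjects per cluster.  Outcomes are clustered binary
responses from a beta-binomial mechanism: cluster j in an arm with prevalence
pi draws a success probability

    P_j ~ Beta(alpha, beta),   alpha = pi (1 - rho) / rho,
                               beta = (1 - pi)(1 - rho) / rho,

and its subjects are i.i.d. Bernoulli(P_j).  This moment-matching
parametrization fixes E[P_j] = pi and makes the pairwise within-cluster
outcome correlation exactly 1/(alpha + beta + 1) = rho.  At rho = 0 the Beta
degenerates; the generator then uses plain Bernoulli(pi), avoiding infinite
parameters.  Default prevalences are 0.40 (control) and 0.30 (intervention),
so the *marginal* treatment log odds ratio is
log[(0.3/0.7)/(0.4/0.6)] = -0.44183.  Because the mechanism fixes
arm-level unconditional probabilities, the simulated treatment effect has a
population-averaged interpretation.

Each subject also carries an auxiliary Bernoulli(0.5) covariate, drawn
independently of arm and outcome before any missingness.  Missingness is
covariate-dependent (CDM, a special case of missing at random): outcomes are
deleted independently with probability p0 for covariate-0 subjects and
p1 = 1.3 p0 for covariate-1 subjects, with p0 = 2 r / 2.3 chosen so the
overall expected missing fraction is r (0, 0.15 or 0.30 in the study grid).
"1.3 times more likely" is read as a **probability ratio**, not an odds
ratio; at these rates the two readings differ by under a percent, but the
probability ratio is the simpler mechanism and is what the generator
implements.  Covariates and arm are never missing.  The default scenario
grid is 5/arm x 500 at rho in {0.001, 0.01, 0.05}, 20/arm x 50 at
{0.01, 0.05, 0.1}, and 30/arm x 30 at {0.05, 0.1, 0.2}, 1000 replications.

What the generator does **not** emulate: unequal cluster sizes or cluster
counts, matched or stratified randomization, missing covariates, and
missingness that depends on outcomes (MNAR).  Passing tests therefore say
nothing about robustness to those features of real trials.

## Population-averaged analysis (GEE)

`ExchangeableGEE` fits logit Pr(y = 1) = beta0 + beta1 * arm by generalized
estimating equations with an exchangeable working correlation.  Details:

* Fisher scoring with the working correlation refreshed each step from the
  moment estimator on standardized Pearson residual cross-products, with
  denominator sum_j m_j(m_j - 1)/2 - p (p = 2 regression parameters).
  Convergence when the largest coefficient update falls below 1e-6; at most
  100 iterations; divergence (|beta| > 30, e.g. an arm without events) and
  singular steps are flagged `converged_ = False`.
* The exchangeable inverse correlation is applied in closed form
  (Sherman-Morrison), so each iteration is a set of grouped sums — no
  per-cluster matrices.
* Variance: the robust sandwich clustered on cluster id, with the treatment
  SE multiplied by **sqrt(J/(J-1))** (J = clusters per arm; equivalently
  J/(J-1) on the variance).  With few clusters the plug-in meat is biased
  down by roughly (J-1)/J because per-arm residuals are centered at fitted
  arm means; the factor undoes this, and the corrected mean SE matches the
  analytic sqrt(VIF (1/(N pi_t q_t) + 1/(N pi_c q_c))) closed form in the
  complete-data scenarios.
* Non-MI confidence intervals are Wald z intervals.  With 5 clusters per
  arm this yields the mild undercoverage (~0.91) characteristic of
  sandwich-based small-sample inference; a t reference would mask it.

## Cluster-specific analysis (random-intercept logistic regression)

`RandomInterceptLogit` maximizes the marginal likelihood of
logit Pr(y_jl = 1) = x_jl' beta + U_j, U_j ~ N(0, sigma_B^2):

* Each cluster's integral over U_j is evaluated by **adaptive Gauss-Hermite
  quadrature**: nodes centered at the cluster's conditional mode (found by a
  safeguarded Newton iteration on the concave integrand) and scaled by the
  local curvature, combined by log-sum-exp.  Default 21 nodes; on
  small-cluster fixtures the truncation error is ~2e-5 at 5 nodes, ~3e-9 at
  11, and below 1e-13 at 21, so 21 nodes is numerically exact here.  When
  the linear predictor is constant within clusters (the trial model), the
  cluster likelihood reduces to its (size, success-count) sufficient
  statistics, making full-scale simulation affordable.
* Optimization is quasi-Newton (BFGS) over (beta, log sigma_B).  The log
  parametrization keeps the variance positive; fits whose variance collapses
  below 1e-8 are flagged `boundary_` — the analogue of the negative-variance
  failures that unconstrained mixed-model software reports — and both
  boundary and optimizer failures are excluded from scenario metrics, with
  counts recorded.  At very small true ICC (rho = 0.001 with 10 clusters)
  the ML variance estimate genuinely sits at the boundary in a large
  fraction of replicates, so these exclusions are frequent there.
* SEs come from the inverse of a central-difference observed-information
  matrix on the natural (beta, sigma_B^2) scale; non-finite or non-PD
  information marks the fit non-converged.  Non-MI intervals are Wald z.
* Starting values: one IRLS step for beta; sigma_B from the residual
  variance of shrunken cluster-level empirical logits.

The implementation was cross-checked against an independent dense-grid
integration oracle (and agrees with `lme4::glmer` at nAGQ = 21 to ~1e-5 in
coefficients, SEs and log-likelihood).

The conditional (cluster-specific) effect is larger in magnitude than the
marginal one; the package uses the attenuation relation
beta_marginal = beta_conditional (1 - rho) to define the conditional truth
for RELR metrics (a `relr_truth="marginal"` switch evaluates RELR against
the marginal truth instead; at rho = 0.001 the two are indistinguishable).
Note the relation is approximate: for the beta-binomial generator the exact
latent-logit variance of a cluster is trigamma(alpha) + trigamma(beta),
which is what the variance-recovery tests use as their oracle — the common
rho pi^2/3/(1-rho) mapping understates it by ~45% at rho = 0.1.

## Missing-data strategies

* **Complete case**: rows with missing outcome are dropped; under CDM this
  is valid but loses efficiency.
* **Standard MI** (`PosteriorDrawImputer`): logistic regression of the
  observed outcomes on treatment and the auxiliary covariate (the variable
  driving missingness), fit by ML (statsmodels GLM).  For each of M = 5
  imputations, coefficients are drawn as beta_tilde = beta_hat + L Z with
  L L' = V the estimated covariance (Cholesky; a relative 1e-6 ridge is
  added only if the factorization fails numerically), each missing subject's
  probability is expit(x' beta_tilde), and the value is imputed by a uniform
  draw.  The model deliberately treats subjects as independent — imputation
  reflects the population-averaged effect and ignores clustering, which is
  exactly the behavior whose consequences the simulation measures.
  Perfect separation or degenerate observed outcomes flag the strategy
  inapplicable for that dataset.
* **Within-cluster MI** (`WithinClusterImputer`): the same posterior-draw
  recipe applied independently inside each cluster that has missing
  outcomes.  Treatment is constant within a cluster and is dropped
  (intercept + auxiliary covariate; intercept only if the observed covariate
  does not vary).  If any such cluster has no observed outcomes or all
  observed outcomes identical, the strategy is inapplicable for the whole
  dataset — with 30-subject clusters and 30% missingness this happens in
  most replicates, which is why those grid cells are reported NA.

Observed values are never altered by any strategy, and all M completed
datasets agree on the observed cells.

## Pooling and metrics

Per-imputation estimates are combined by Rubin's rules
(beta_bar = mean, V = W + (1 + 1/M) B) with the **Barnard-Rubin** adjusted
degrees of freedom: 1/nu_adj = 1/nu_M + 1/nu_obs, where
nu_M = (M-1)[1 + (M/(M+1)) W/B]^2 and
nu_obs = ((nu_com+1)/(nu_com+3)) nu_com (1 - gamma),
gamma = (1+1/M) B/V, and nu_com = 2(k-1) for k clusters per arm (k > 2
required).  B = 0 yields nu_adj = nu_obs (nu_M is infinite).  MI intervals
use t with nu_adj df; direct analyses use z.  Pooling of variance
components across imputations is out of scope.

Scenario metrics over the surviving replicates: standardized bias
|mean - truth| / sd (sample sd; reported as 0 when sd = 0 and the bias is
also 0, NA otherwise), mean model-based SE (the table-facing "empirical
standard error" convention; the sd of the estimates is also emitted as
`sd_of_estimates`), RMSE = sqrt(mean (est - truth)^2), and coverage of the
nominal intervals.  Replicates excluded for non-convergence or MI
inapplicability are counted per cell; a cell failing in more than half its
replicates is NA.

## Simulation driver and problem sizes

Within a replicate, one generated dataset (and one missingness pattern) is
shared by every strategy and analyzer: replicate random streams are keyed
by (design, ICC, missing rate, replicate index) only, so cross-method
contrasts are paired and a cell rerun with the same master seed is
bit-reproducible.  MI draws use separate per-strategy streams.

The acceptance script runs its cells at the study scale of 1000
replications.  The test suite's Monte-Carlo cells are sized per check — the
complete-data S-design cell runs the full 1000 replications because
standardized bias carries MC error ~1/sqrt(n), while SE, RMSE and coverage
checks use 150-600 replications, at which their MC error is comfortably
inside the asserted tolerances (binomial SE of a 0.95 coverage at 400-600
replicates is ~0.01); the documented MC-error columns in `run_grid` output
make this auditable.

## Known limitations

* Balanced, completely randomized two-arm designs only; no covariate
  adjustment beyond treatment; exchangeable working correlation only; the
  single sqrt(J/(J-1)) sandwich correction (no Kauermann-Carroll or
  Mancl-DeRouen variants); no MI by random-effects logistic regression.
* Cluster-specific (random-intercept) Wald inference with 5 clusters per
  arm is fragile: the variance component is frequently estimated at the
  boundary, information-based SEs understate sampling variability as the
  design effect grows, and coverage degrades accordingly.  Results from
  legacy mixed-model software in this regime are sensitive to its optimizer
  and parametrization; this package reports the faithful ML answer, with
  boundary and failure counts exposed rather than folded into estimates.
* The convergence-failure bookkeeping emulates analysis practice
  (exclusion of failed replicates), not any particular software's internal
  failure modes.
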