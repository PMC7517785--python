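# Methods

## Model

`lgcdm` implements cognitive diagnostic models for longitudinal binary item
responses in which the measurement layer is the reparameterized DINA (RDINA)
and the structural layer is a latent growth curve on each attribute-mastery
logit.

**Measurement.** Given a Q-matrix `q_jk` declaring which of K attributes each
of J items requires, the ideal response is conjunctive,
`eta_ij = prod_k alpha_ik^(q_jk)`, and

    logit P(Y_ij = 1 | eta_ij) = f_j + d_j * eta_ij

`f_j` is the false-alarm logit and `d_j` the discrimination logit; classical
guessing and slip are `g_j = logistic(f_j)` and `s_j = 1 - logistic(f_j + d_j)`.
`d_j` is unconstrained during estimation; a warning flags non-monotone items
(`d_j < 0`) at convergence.

**Structure.** For person i, occasion t (coded 0, 1, ... with pretest = 0) and
attribute k,

    logit P(alpha_itk = 1) = b_k + h_k z_i
                             + (lam0 + h0 z_i) u_i
                             + (lam1 + h1 z_i) v_i t
                             + eps_sd * eps_itk

with u_i, v_i iid standard normal (person random intercept and slope factors)
and eps_itk iid standard normal (time-specific disturbance). The factors'
means and variances are fixed at 0 and 1 for identification; the free
parameters `lam0`, `lam1` are the intercept and slope *loadings* (the random
effects' SDs on the logit scale), and the covariate effects are the
attribute-level main effect `h_k` plus shifts `h0`, `h1` of the two loadings.
A frequently printed alternative treats the growth parameters as free factor
*means* with unit SDs; that parameterization is rank-deficient (a free
intercept mean is indistinguishable from a common shift of all `b_k`, and in
the conditional model a mean treatment shift of the intercept is
indistinguishable from a common shift of all `h_k`), so this package uses the
loadings form, under which every parameter is locally identified — the
`check_local_identification` Jacobian-rank check verifies this numerically at
any parameter point.

Attribute indicators are conditionally independent across attributes and
occasions given (u, v, eps, z, t); this is the growth-curve analogue of local
independence and makes the model a complete generative recipe.

**Model menu.** `lg_uncond` (no covariate terms) and `lg_cond` as above;
`rdina` and `rdina_cov` are the no-growth baselines with a single mastery
profile per person held constant across occasions (occasions stacked, item
parameters tied). The stacked convention is what makes the baselines genuine
misspecifications of longitudinal data — fitting each occasion as an
independent case would be nearly well specified marginally and would not
expose the cost of ignoring growth.

**Item-level growth.** The variant that puts the time slope on the item logit
(`item_growth_logit`) is provided for simulation and extension only; no
estimator is attached.

## Estimation

The marginal likelihood integrates (u, v) on a tensor-product Gauss–Hermite
grid (default 9 nodes per dimension; the study harness uses 7) and, when
`eps_sd > 0`, integrates each eps_itk by a one-dimensional rule inside the
attribute probabilities. Within a node, the 2^K mastery profiles are
enumerated per occasion. The E-step is fully vectorized (batched
matrix products over persons x nodes x occasions x profiles); its aggregated
sufficient statistics drive

* a damped Newton update of each item's (f_j, d_j) — a weighted two-group
  logistic regression with closed-form gradient and Hessian, and
* a bounded quasi-Newton (L-BFGS-B) update of the attribute block with
  analytic gradients (generalized EM: the update is accepted only if it
  improves the expected complete-data log-likelihood, which preserves EM's
  monotonicity).

After EM (relative penalized-loglik change < 1e-9, cap 500 iterations) the
full free-parameter vector is polished by L-BFGS-B on the marginal
(penalized) likelihood using the exact score obtained from the E-step via
Fisher's identity. Multi-start: start 1 is deterministic (guessing 0.2, slip
0.2, difficulties and covariate effects 0, loadings 0.5/0.2), later starts
add seeded N(0, 0.5) perturbations with loadings floored at 0.05; each start
runs a short EM burn-in (40 iterations) and the best penalized loglik is run
to convergence. Ties break to the lowest start index.

**Posterior-mode (PM) estimation** (the default) adds an independent
normal(0, sd = 3) prior on every free logit-scale parameter. The prior is
weak (it bounds logits without materially moving interior estimates) and
keeps all-zero or all-one response patterns away from the boundary; with
`prior_sd = 1e6` PM reproduces ML to numerical tolerance.

**Standard errors** come from the outer product of per-person scores (BHHH),
computed analytically from E-step quantities; a singular information matrix
yields missing SEs with a warning, never an exception.

**Numerical choices.** Probabilities are floored at 1e-12 inside logarithms;
item and attribute logits are capped at |15| inside Newton updates; posterior
ties at exactly 0.5 classify as non-mastery (deterministic, with a logged
count); missing responses are missing-at-random and drop out of the item
product.

## Classification statistics

Posterior mastery probabilities condition on a person's complete response
array (all occasions), so evidence flows across occasions through the shared
factors. A "case" is one person-occasion. `P_c` is the frequency-weighted
mean of max(p, 1-p) over unique response patterns; `lambda = (P_c - m)/(1 - m)`
with m the larger marginal class share, i.e. the relative reduction in
classification error over modal assignment. Prevalence is the model-implied
marginal p(alpha_k = 1) from a 41-node quadrature, averaged over occasions
and the empirical covariate distribution.

At the built-in pre/post generating values the model-implied P_c is about
(0.84, 0.92, 0.87, 0.87) for the four attributes — the
ratios-and-proportions attribute is measured by the weakest items (mean slip
0.49) and classifies worst — and MAP agreement with the true simulated
mastery states matches these values, which is the calibration check the test
suite enforces.

## Simulation designs and the recovery harness

`sim1_uncond` / `sim1_cond`: 21 single-attribute items, 4 attributes
(ratios & proportions, measurement & data, number systems, geometry), 2
occasions, n configurable; generating values are the fitted real-data
estimates bundled with the package. The treatment covariate is
Bernoulli(0.5) per person (the allocation ratio of the emulated
cluster-randomized trial is not published; 1:1 is assumed).
`sim2_uncond` / `sim2_cond`: 30 items, 5 attributes (each appearing alone,
in pairs and in triples equally often), 3 occasions. Item
generating values are guessing = slip = 0.2; the growth values are package
defaults (lam0 = 0.5, lam1 = 0.3, b evenly spaced in [-0.5, 0.5], h_k = 0.3,
h0 = 0.2, h1 = 0.1) surfaced in the design metadata.

**Disturbance mode.** The built-in designs set `eps_sd = 0` (generator and
fitter matched). The precision of the real-data estimates these designs emulate — item and
attribute SEs of 0.02–0.43 at n = 879, and recovery MSEs near 0.002 for the
attribute difficulties — is attainable only without an extra
unit-variance disturbance inside the Bernoulli logit, so the absorbed mode is
what those values describe. The integrated mode (`eps_sd = 1`) remains
available and is exercised by the likelihood oracle tests.

**Recovery metrics.** Bias(x) = mean_n(est_n - true), %Bias =
|Bias/true| x 100, MSE = mean_n((est_n - true)^2), per parameter; block
%Bias is the unweighted mean of per-parameter %Bias within a block (item f,
item d, attribute difficulty b, intervention h, random-effect loadings,
loading covariate shifts). Parameters with |true| < 1e-8 are excluded from
%Bias. Non-converged replications are excluded and counted; more than half
failing aborts the study. Replication seeds are spawned deterministically
from the study seed and stay below 2^31.

**Study sizes.** The bundled studies run 25 replications per condition with
7-point quadrature and 2 starts per fit. Two consequences are worth knowing
when reading the output. First, |mean bias|/|true| is a noisy statistic when
truths are tiny: with per-replication SD sigma, its expectation is about
0.8 sigma / (sqrt(R) |true|) even for an unbiased estimator, so the
intervention-effect block (smallest truth 0.02) has a floor of tens of
percent at any feasible R, and the block value should be read as an upper
bound on systematic bias. Second, the slope loading (truth 0.03-0.04)
contributes variance of order 1e-3 to the attribute logits and is therefore
practically unidentifiable at these sample sizes; its %Bias is reported
honestly and is large, and the same limitation applies to the loading shifts
h0/h1.

## What the synthetic data do and do not show

The generator emulates balanced designs with known Q-matrices,
time-constant items, no missingness, independent attributes given the
factors, and a person-level binary covariate. Real assessments add
Q-matrix misspecification, item drift across occasions, planned and
unplanned missingness, clustered randomization, and attribute hierarchies —
none of which these studies probe. Passing recovery therefore shows the
estimator is consistent for its own generative model at realistic sizes,
not that the model is adequate for any particular dataset.

## Known limitations

* The no-growth baselines are estimated only in their attribute-covariate
  form; the item-level covariate effect l_j is representable
  (`rdina_response_prob`) but not fitted.
* Per-attribute random effects (a config switch in spirit) are not
  implemented; heterogeneity across attributes is carried by the fixed b_k.
* No MCMC, no bootstrap SEs, no multiple-group or latent-transition
  parameterizations, no polytomous responses, no attribute hierarchies.
* Quadrature is fixed (non-adaptive); with loadings far above 1 the default
  node counts would need to grow.
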