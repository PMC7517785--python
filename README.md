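# lgcdm — latent growth cognitive diagnostic models

Cognitive diagnostic models (CDMs) classify examinees into binary
skill-mastery profiles from their item responses, but are almost always
applied to a single time point. `lgcdm` is for the longitudinal case —
pre/post and multi-wave assessments where the question is how attribute
mastery *changes*, and whether an intervention changed it. It is aimed at
psychometricians and education researchers analyzing repeated diagnostic
assessments, and at methodologists who need a transparent, testable
reference implementation with a simulation harness.

## The model

The measurement layer is the reparameterized DINA (RDINA). With a Q-matrix
`q_jk` declaring which attributes item `j` requires, the ideal response is
conjunctive, `eta_ij = prod_k alpha_ik^(q_jk)`, and

    logit P(Y_ij = 1 | eta_ij) = f_j + d_j * eta_ij

so guessing and slip are `g_j = logistic(f_j)` and
`s_j = 1 - logistic(f_j + d_j)`.

The structural layer puts a latent growth curve on each attribute-mastery
logit. For person `i`, occasion `t` (pretest coded 0) and attribute `k`:

    logit P(alpha_itk = 1) = b_k + h_k z_i
                             + (lam0 + h0 z_i) u_i
                             + (lam1 + h1 z_i) v_i t
                             + eps_sd * eps_itk

with standard-normal person factors `u_i` (intercept), `v_i` (slope) and
time-specific disturbance `eps_itk`. `b_k` is the attribute difficulty,
`lam0`/`lam1` are the random-effect loadings (SDs on the logit scale), and a
binary covariate `z_i` (e.g. treatment) acts through the attribute-level
effect `h_k` and the loading shifts `h0`, `h1`. Four families are available:
`lg_cond` (above), `lg_uncond` (no covariate), and the no-growth baselines
`rdina` / `rdina_cov` (one mastery profile per person, occasions stacked).

Estimation is marginal maximum likelihood or posterior mode (EM with
Gauss–Hermite quadrature, multi-start, an L-BFGS polish with analytic
scores); classification quality is summarized by the proportion correctly
classified `P_c` and the chance-corrected `lambda`; a simulation module
generates data from all four families and runs Bias / %Bias / MSE
parameter-recovery and cross-fitting studies. See `docs/methods.md` for the
full account.

## Worked example

Simulate a pre/post intervention study from the bundled conditional design
(21 items, 4 attributes, 2 occasions, 1:1 treatment allocation), refit the
generating model, and summarize:

```python
import numpy as np
from lgcdm import fit, guess_slip
from lgcdm.classification import classification_report
from lgcdm.simulation import builtin_design, simulate_dataset

design = builtin_design("sim1_cond", n_persons=1000, seed=7)
data, truth = simulate_dataset(design, seed=7)
result = fit(design.spec, data, n_starts=2, seed=7, compute_se=False)

g, s = guess_slip(result.item_params)
print(f"loglik = {result.loglik:.1f}   AIC = {result.aic:.1f}   BIC = {result.bic:.1f}")
print(f"mean guessing = {g.mean():.2f}   mean slip = {s.mean():.2f}")
print("attribute difficulties:", np.round(result.attr_params.b, 2))
print("treatment effects h_k :", np.round(result.attr_params.h, 2))
rep = classification_report(result, data)
print("Pc      :", np.round(rep.pc, 2))
print("lambda  :", np.round(rep.lam, 2))
```

Output:

```
loglik = -24590.6   AIC = 49289.2   BIC = 49554.2
mean guessing = 0.22   mean slip = 0.36
attribute difficulties: [-0.39  0.01 -0.53 -0.17]
treatment effects h_k : [0.11 0.06 0.16 0.33]
Pc      : [0.84 0.93 0.87 0.87]
lambda  : [0.63 0.86 0.68 0.73]
```

The mean guessing/slip (0.22 / 0.36) recover the generating instrument; the
difficulties and treatment effects sit within sampling error of the
generating values (b = [-0.45, -0.04, -0.44, -0.11], h = [0.40, 0.09, 0.02,
0.24] — single-replication noise on `h_k` is roughly ±0.15 at n = 1000,
which is exactly why the recovery harness averages over replications).
`P_c` says, e.g., that 93% of person-occasions are correctly classified on
the measurement-and-data attribute; `lambda` corrects that for chance
agreement with the modal class. The ratios-and-proportions attribute (first
entry) is measured by the weakest items (mean slip 0.49) and classifies
worst — visible in both statistics.

The same workflow is available from the shell:

```sh
lgcdm simulate --design sim1_cond --n 1000 --seed 7 --out data.csv
# writes data.csv plus data.qmatrix.csv and data.covariates.csv
lgcdm fit --data data.csv --qmatrix data.qmatrix.csv \
          --covariates data.covariates.csv --model lg_cond --out fit.json
lgcdm classify --fit fit.json --data data.csv --out report.csv
lgcdm recover --design sim1_uncond --n 1000 --reps 25 --seed 1 --out rec.csv
```

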