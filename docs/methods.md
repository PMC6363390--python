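# Methods

## Model

Each trial offers a fixed immediate option (4 coins now) against a
later option (*V* coins at delay *T*, in the task's native time unit:
seconds for NV/SV, days for LV/DV, weeks for WV). Subjective value is
hyperbolic, `U = V/(1 + kT)`; choice follows a softmax on the utility
difference with noise τ. The hierarchical model has, for tasks
*t* and subjects *n*:

    logk[n,t] = mu_logk[t] + (diag(sd_logk) · L · z[n])[t]     z[n] ~ N(0, I)
    log tau[n,t] = mu_logtau[t] + sd_logtau · u[n]             u[n] ~ N(0, 1)
    P(later) = logistic((V/(1+kT) − S) / tau)

`L` is the Cholesky factor of the cross-task correlation of subject
log(k) effects; the per-subject noise deviation is shared across tasks
with task-level fixed effects. Rates are fit in native units and
converted explicitly (`1 day = 86400 s`, `1 week = 7 days`), because
the unit shift of log(k) — ln 86400 ≈ 11.37, ln 7 ≈ 1.95 — is itself a
quantity of scientific interest (the "subjects ignore units"
prediction).

The expanded model adds a per-subject, per-horizon (short/long)
*reward scaling* ρ that multiplies both offers' magnitudes. With
linear utility a population-level ρ trades off against τ; what the
expanded model genuinely adds is per-subject heterogeneity in reward
experience per horizon, and that is what the K-fold comparison
detects.

## Inference

No NUTS-style sampler is available in this environment, so the
hierarchical posterior is computed by a marginal-Laplace scheme of the
kind used by lme4/glmmTMB/INLA, written here with analytic gradients:

1. **Inner problem.** Given hyperparameters η, the subject latents
   (3 correlated log(k) deviations + 1 noise deviation, + 2 reward
   scaling in the expanded model) are independent across subjects.
   Their modes are found by damped Newton, vectorized over subjects,
   with exact analytic per-subject gradients and Hessians (verified
   against finite differences at 1e-8).
2. **Outer problem.** η (population means, random-effect SDs on a log
   link, correlation via tanh of canonical partial correlations) is
   optimized by L-BFGS on the Laplace-approximate marginal posterior.
   Priors: mu_logk ~ N(−3, 3) per task (covering the log-rate ranges
   reported across large populations), sd_logk ~ half-N(0, 2),
   mu_logtau ~ N(0, 1), sd_logtau ~ half-N(0, 1), atanh partial
   correlations ~ N(0, 1), log ρ population levels ~ N(0, 0.5)
   (centered at ρ = 1) with sd ~ half-N(0, 0.5). A plain LKJ prior
   would need the CPC Jacobian; the normal-on-raw prior is an
   equivalent-strength weakly informative substitute and is what the
   package uses.
3. **Draws.** The hyperparameter posterior is approximated by a
   Gaussian at its mode (dense finite-difference Hessian); each η draw
   re-solves the inner modes and draws subject latents from their
   conditional Gaussians. Joint MAP in the non-centered
   parameterization is *not* used anywhere: its mode is degenerate in
   the random-effect scales (it inflates sd while shrinking z), which
   the marginal-Laplace route avoids.

An `emcee` ensemble-MCMC backend samples the full joint posterior and
serves as the asymptotically exact cross-check; the test suite
verifies that both routes agree on population-level posteriors of a
small cohort. Split-group R-hat over walker groups gates the MCMC
route at 1.05.

Per-subject MLE uses L-BFGS-B over (logk, log τ [, log α, log ρ]) with
a 5-point multi-start grid over logk ∈ [−12, 2] (3 starts in large
replicate loops), standard errors from the inverse observed
information, and flagging (not fitting) of delay-insensitive subjects
(all-later or all-sooner — the operational insensitivity rule; the
fraction-later ∈ {0, 1} threshold is a package choice). Leave-one-
trial-out CV warm-starts each fold at the full-data optimum.

The adaptation analysis fits a mixed-effects logistic regression
(fixed effects: ΔU, task, early, task:ΔU, task:early; random
intercept + ΔU slope per subject) by Laplace-approximate ML; it
reproduces lme4::glmer coefficients and log-likelihoods to ~1e-3 on
test data (the suite runs that comparison through Rscript). The
linear days/verbal variance-decomposition model uses statsmodels
MixedLM with ML (not REML) so nested LR tests on fixed effects are
valid.

## Synthetic cohorts

The generator emulates the study design: 63 subjects by default;
blocked offer schedules over 5 delays {3, 6.5, 14, 30, 64} × 5
magnitudes {1, 2, 5, 8, 10} against 4 coins now; smaller-later catch
offers are 25% of later offers in NV and 10% in verbal tasks, with all
larger-later offers equally likely and the smaller-later mass split
evenly between magnitudes 1 and 2; block lengths jitter ±1 trial
around n/5; NV spans three sessions (300 trials; session 1 is dropped
by the preparation filter, leaving 200) and verbal tasks span two
sessions (160 trials). The DV/WV control grids (1–64 days, 1–35
weeks) are 5-point roughly log-spaced, since only the ranges are
specified. Subject log(k) is drawn jointly normal across tasks with
correlation (NV–SV 0.8, SV–LV 0.6, NV–LV 0.4), means (−3.2, −3.49,
−3.95) and SD 1.0 per task; noise means are τ = 1.5 (NV) and 0.8
(verbal), with a shared lognormal subject deviation of SD 0.3 — the
published estimates fix the means and the NV > verbal noise ordering;
the SDs are package choices on the 0–10 coin utility scale.

What the generator does **not** emulate: learning-stage dynamics,
lapses/attention failures beyond softmax noise, reaction times,
within-session drift, and any true adaptation process (the adaptation
analysis is validated on logit-simulated records with a known
interaction instead). Passing tests therefore demonstrate estimator
correctness and power under the assumed generative model, not
robustness to real-data artifacts.

## Numerical choices

Choice probabilities are clipped to [1e-12, 1−1e-12] inside
log-likelihoods; softmax is computed overflow-safely; the matching
rule is evaluated as a softmax on log-utilities, making its scale
invariance exact. Inner Newton Hessians are eigenvalue-floored and
line-searched; conditional draw curvatures are floored at 0.5 (the
latent prior alone contributes 1). BIC is p·ln(n) + 2·NLL; class
selection takes the lowest mean per-subject BIC with ties toward fewer
parameters, reporting alongside the count of subjects with McFadden
pseudo-R² ≥ 0.2 ("well described" — the threshold is a package
choice). K-fold IC stratifies folds by subject × task so every
training set retains all subjects, and pairwise ΔIC standard errors
use pointwise held-out contributions.

The attenuation ceiling for rank correlations is estimated by
simulating cohorts whose true log(k) ranks agree perfectly across two
tasks, running the same MLE pipeline on both, and averaging the
Spearman correlation over replicates (500 by default; fewer in tests);
corrected = observed / ceiling, capped at 1 with a flag.

## Problem sizes used in tests and the acceptance script

Chosen so the full pipeline exercises every stage at desk scale:
posterior-coverage checks use 20 cohorts of 20 subjects × 60
trials × 3 tasks (5 cohorts in the acceptance script);
correlation-ordering checks use 63 subjects × 100 trials with 20 (10)
replicates; model-class recovery uses 160 trials/subject (K-fold with
k = 5 folds at that scale; the pipeline default is k = 10); the
calibration studies use 1,000 null simulations (bootstrap at n = 63,
the study's sample size, where the percentile bootstrap is well
calibrated; the adaptation LR at 8 subjects × 40 trials/task). The
main acceptance pipeline runs 30 subjects × 100 trials × 3 tasks.

## Limitations

The Laplace posterior is Gaussian in the hyperparameters; extreme
skew (tiny cohorts, boundary SDs) is better served by the emcee
backend. Coverage statements are calibrated for the population means;
credible intervals for variance parameters inherit the usual Laplace
optimism. The trial-number / cumulative-waiting-time covariate models
and quasi-hyperbolic (β–δ) discounting are out of scope, as are
reaction-time and session-timing analyses.
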