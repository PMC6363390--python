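# discountfit

Delay-discounting analysis across task contexts: simulation, model
fitting and reliability statistics for intertemporal-choice experiments
in which the same subjects choose between a fixed immediate reward and
a larger-later reward in several task contexts — a non-verbal
experiential task with delays in seconds (NV), a verbal task with
delays in seconds (SV), and a verbal task with delays in days (LV),
plus days/weeks control tasks (DV/WV).

The scientific questions the package addresses:

* **Reliability** — do subjects keep their rank order of impulsivity
  across the verbal/non-verbal gap and across a four-orders-of-magnitude
  change in time-horizon?
* **Temporal context** — how do the *magnitudes* of discount rates
  shift and scale between contexts, and can unit-conversion,
  magnitude effects, or early-trial adaptation explain it?

## The model

Choices are modelled with hyperbolic discounting plus softmax decision
noise. A delayed reward of magnitude *V* at delay *T* has utility

    U = V / (1 + k·T)

with discount rate *k* (units 1/time, fit in each task's native unit),
and the probability of choosing the later option is

    P(later) = exp(U_L/τ) / (exp(U_L/τ) + exp(U_S/τ))

with per-subject decision noise τ. Alternative model classes
(exponential utility `V·e^(−kT)`, a scale-invariant matching rule,
utility curvature `V^α`, per-horizon reward scaling ρ) are available
for model comparison by per-subject BIC, leave-one-trial-out CV and
K-fold information criteria.

The central estimator is a Bayesian hierarchical model: population
log(k) and log(τ) per task, per-subject zero-mean deviations of log(k)
correlated across tasks, and a shared per-subject noise deviation —
`logk ~ task + (task | subject)`, `noise ~ task + (1 | subject)`.
Inference uses a Laplace-approximate marginal likelihood (subject
latents integrated out per subject, as in lme4/glmmTMB) with posterior
draws from a hierarchical Gaussian approximation; an ensemble-MCMC
backend (emcee) provides an asymptotically exact cross-check.

## Worked example

```python
from discountfit import (PopulationConfig, simulate_cohort, prepare_dataset,
                         FilterPolicy, fit_hierarchical, HierarchicalConfig,
                         posterior_summary)

# a study-shaped synthetic cohort: 63 subjects x 3 tasks
dataset, agents = simulate_cohort(PopulationConfig(n_subjects=63), seed=1)
dataset = prepare_dataset(dataset, FilterPolicy())   # drops NV session 1

fit = fit_hierarchical(dataset, HierarchicalConfig(n_draws=800), seed=1)
for task in ("NV", "SV", "LV"):
    s = posterior_summary(fit, f"mu_logk[{task}]")
    print(task, round(s["mean"], 2), [round(v, 2) for v in s["ci95"]])
```

prints (population posterior mean log discount factor per task, with
95% credible interval; NV/SV in 1/s, LV in 1/day):

```
NV -3.09 [-3.31, -2.86]
SV -3.39 [-3.62, -3.16]
LV -3.95 [-4.21, -3.69]
```

Each population mean recovers its generating value (−3.2, −3.49,
−3.95) within the credible interval of this one simulated cohort: a
subject with log(k) ≈ −3 per second values 10 coins at half
value after about 20 s, so these cohorts discount steeply per second in
the short tasks and almost identically *per day* in the long task —
the temporal-context scaling the package's analyses quantify.

The same pipeline is scriptable from a shell:

```sh
discountfit simulate --seed 1 --out runs/sim
discountfit fit runs/sim/trials.csv --seed 1 --out runs/fit
discountfit report runs/fit --out runs/report
```

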