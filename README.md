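# recurfrail

Gap-time survival analysis of **recurrent episodes** — such as repeated
sickness-absence spells of the same worker — with piecewise-exponential
(Poisson) hazard regression that accounts for the two sources of
within-individual correlation:

* **event dependence** — the hazard of ending the *k*-th episode differs from
  the first one's — handled by stratifying the baseline hazard by event order;
* **heterogeneity (frailty)** — some individuals are systematically faster or
  slower to recover for unmeasured reasons — handled by a multiplicative
  gamma-distributed random effect shared by all episodes of an individual.

The centre piece is the **conditional frailty Poisson model (CFPM)**: for
individual *i*, event order *k* and gap time *t* (days since the episode
started),

```
lambda_ik(t) = lambda_0k(t) * exp(x_ik' beta + omega_i)
lambda_0k(t) = sum_j lambda_jk * 1{ t in (tau_j, tau_{j+1}] }
```

with `u_i = exp(omega_i) ~ Gamma(mean 1, variance theta)`. Episodes are
expanded into person-period records over the interval grid `0 = tau_1 <
tau_2 < ...` (default interval length 90 days); the event indicator `d_jik`
is then Poisson with log-linear mean `log lambda_jk + x' beta + omega_i +
log n_jik`, where the time at risk `n_jik` enters as an offset. The frailty
is integrated out in closed form via gamma–Poisson conjugacy, which makes
the model fast enough for registry-scale data where partial-likelihood
frailty models become computationally painful. Dropping the frailty gives
the conditional Poisson model (**CPM**); dropping the order stratification
gives the frailty Poisson model (**FPM**). With 1-day intervals the CPM
reproduces the event-order-stratified gap-time Cox estimates (Breslow ties)
— the classical Poisson–Cox equivalence.

The package also ships:

* the `%RB` / `%RW` model-comparison statistics (percent relative bias in
  hazard ratios and percent relative difference in 95% CI width against a
  reference model, conventionally the Cox-based conditional frailty model),
  together with transcriptions of published reference tables for two
  diagnosis groups so the published comparisons recompute offline;
* a synthetic-cohort simulator that is the generative twin of the CFPM
  (order-specific piecewise-constant baselines, gamma frailty, categorical
  covariates, right censoring), used for parameter-recovery validation;
* a `recurfrail` command line (`simulate`, `expand`, `fit`, `compare`).

## Worked example

Simulate a heterogeneous cohort (1,000 workers, true `HR[Female] = 0.8`,
frailty variance `theta = 0.5`, order-2 spells ending 1.5x faster), expand
it on a 90-day grid, and fit the conditional Poisson model with and without
frailty:

```python
import numpy as np
from recurfrail import *

cfg = SimulationConfig(
    n_individuals=1000,
    grid=IntervalGrid((0,)),
    baseline_rates=np.array([[0.02, 0.03]]),   # order-2 spells end 1.5x faster
    beta={"sex": {"Female": np.log(0.8)}},
    covariate_probs={"sex": {"Male": 0.5, "Female": 0.5}},
    theta=0.5, max_episodes=8, followup_days=150, k_max=2)
cohort, truth = simulate_cohort(cfg, seed=42)
print(validate_cohort(cohort).summary())

grid = grid_from_durations(cohort.episodes["duration_days"], 90)
pp = expand_cohort(cohort, grid)
for name in ("cpm", "cfpm"):
    res = fit(pp, MODEL_SPECS[name], cohort.schema, grid=grid)
    row = res.params.iloc[0]
    print(f"{name}: HR[Female] = {row.hr:.3f} ({row.ci_low:.3f}-{row.ci_high:.3f}), "
          f"theta = {res.theta:.3f}, log-lik = {res.log_likelihood:.1f}")
```

prints

```
individuals: 1000
episodes: 4166 (3305 events, 861 censored)
episodes per order: k=1: 1000, k=2: 3166
violations: 0
cpm: HR[Female] = 0.911 (0.851-0.976), theta = 0.000, log-lik = -6714.2
cfpm: HR[Female] = 0.875 (0.787-0.972), theta = 0.409, log-lik = -6610.2
```

Ignoring the frailty (CPM) attenuates the covariate effect toward the null
(0.911 versus a truth of 0.8) and narrows the interval; the CFPM recovers
both the effect (0.875, CI covering 0.8) and the heterogeneity
(`theta = 0.41` against a truth of 0.5 in this single replicate), and its
higher log-likelihood reflects the extra correlation it captures.

The same pipeline from a shell:

```
recurfrail simulate src/recurfrail/data/scenarios/neoplasms_like.yaml cohort.csv --seed 1
recurfrail expand cohort.csv pp.csv --interval-length 90 --k-max 5
recurfrail fit pp.csv fit_cfpm.csv --model cfpm
recurfrail fit pp.csv fit_cpm.csv --model cpm
recurfrail compare fit_cpm.csv fit_cfpm.csv comparison.csv
```

## Comparing models against a reference

`compare_tables` computes, per covariate contrast,

```
%RB = (HR_other - HR_ref) / HR_ref * 100
%RW = ((U_o - L_o) - (U_r - L_r)) / (U_r - L_r) * 100
```

`load_reference_tables("mental_disorders" | "neoplasms")` returns the
packaged transcriptions of published hazard-ratio tables (six models each:
CFPM, CPM, FPM and the Cox-based CM, FM, CFM), from which the published
comparison tables recompute at one-decimal rounding.

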