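# Methods

## Model family

All three fitters estimate a gap-time hazard for the end of a recurrent
episode. Time resets at each event, so the survival time of the `k`-th
episode of individual `i` is its duration in days. The hazard is

    lambda_ik(t) = lambda_0k(t) * exp(x_ik' beta + omega_i),

where `lambda_0k(t)` is piecewise constant on a grid of left-open
right-closed intervals `(tau_j, tau_{j+1}]` with `tau_1 = 0` and an
open-ended final interval. The three models differ in which terms they keep:

| model | baseline index | frailty |
|-------|----------------|---------|
| CPM   | (interval, event order) | no |
| FPM   | interval only           | yes |
| CFPM  | (interval, event order) | yes |

Order-specific baselines capture event dependence; the frailty
`u_i = exp(omega_i)`, gamma with mean 1 and variance `theta`
(shape = rate = `1/theta`), captures heterogeneity. Mean 1 is the
identifiable normalisation for a multiplicative random effect — any other
mean is absorbed by the baseline.

### Person-period likelihood

Each episode is split into one record per overlapped interval with exposure
`n_jik` (days at risk in the interval, summing exactly to the duration) and
event indicator `d_jik` (1 only on the terminal record of an uncensored
episode). Conditional on the frailty, `d_jik` is treated as Poisson with
mean `u_i * n_jik * lambda_jk * exp(x'beta)` — the piecewise-exponential
likelihood, exact up to the discreteness of day counts. Because durations
are whole days, a duration equal to a cut point belongs to the earlier
interval, and the minimal episode duration is 1 day (a same-day spell still
contributes one day of exposure; zero-length risk periods cannot).

The frailty is integrated analytically. With `a = 1/theta`,
`D_i = sum d_jik` and `M_i = sum mu_jik` over the records of individual `i`:

    log L_i = sum d*log(mu) + log G(a + D_i) - log G(a) + a*log a
              - (a + D_i) * log(a + M_i).

Numerically this is evaluated as

    sum_{r < D_i} log(a + r)  -  a*log1p(M_i / a)  -  D_i*log(a + M_i),

using the fact that `D_i` is an integer count. The naive `gammaln`
difference loses ~1e-3 absolute accuracy at `theta = 1e-12` (where
`a = 1e12`); the product form is exact, and the whole expression converges
to the fixed-effects Poisson log-likelihood as `theta -> 0` (validated to
1e-6 relative at `theta = 1e-12`, and against adaptive quadrature to better
than 1e-8 relative elsewhere).

### Estimation

* **Fixed-effects models** (CPM, or FPM with `theta` fixed at 0) are fitted
  by profile likelihood: given `beta`, each baseline cell's log-hazard has
  the closed form `log(events / sum of n*exp(x'beta))`, so only `beta` is
  optimised (BFGS, analytic envelope gradient, gradient tolerance 1e-8).
  This makes the cell count irrelevant to the optimisation dimension —
  including the 1-day-interval limit, where the profiled Poisson fit equals
  the event-order-stratified Cox partial likelihood with Breslow tie
  handling (verified to ~1e-7 on the log-HR scale).
* **Frailty models** optimise `(baseline, beta, log theta)` jointly by
  L-BFGS-B with analytic gradients, warm-started from the fixed-effects fit
  and `log theta = log 0.5`; `theta` is optimised on the log scale with
  bounds `[1e-8, 1e3]`. An estimate below 1e-6 is reported as the boundary
  value 0 with a flag. Tolerances: `ftol 1e-12`, `gtol 1e-7`; hitting the
  iteration cap sets `converged=False` instead of raising.
* **Standard errors** are Wald at the optimum. For fixed-effects fits the
  covariance of `beta` comes from the exact blocked Hessian via the Schur
  complement of the (diagonal) baseline block; for frailty fits the full
  observed information is obtained by central finite differences of the
  analytic gradient. 95% CIs are `exp(beta +/- 1.96 se)`. When `theta` is
  on the boundary its row/column is dropped from the information.
* **Unidentified baseline cells** (positive exposure, zero events) have
  their MLE at -infinity; they are pinned at log-hazard -20, excluded from
  the free parameters, and reported with a warning naming the cells. The
  remaining estimates are unaffected — this mirrors how such risk sets drop
  out of a partial likelihood. `zero_event_cells` lets users find them
  before fitting and coarsen the grid instead.

### Baseline parameterisation

One free log-hazard per (interval) or (interval x order) cell and *no*
intercept: covariates are treatment-coded contrasts against each schema's
reference level, baselines carry the levels. This avoids aliasing decisions
and makes `predict_episode_hazard` a plain `exp(alpha_jk + x'beta)` (frailty
at its mean).

## Interval grid

The default interval length is 90 days. The number of intervals is
data-driven: the maximum observed duration rounded up to a whole interval;
cells beyond the data are never created. The piecewise-constant
approximation trades bias (long intervals) against sparse, unstable cells
(short intervals); no general rule exists, so `sensitivity_fit` refits one
model over a list of interval lengths for a cut-point sensitivity analysis.
Note the Poisson log-likelihood contains the layout-dependent offset term
`sum d*log n`; across different grids, fits are comparable only after
subtracting it (the survival log-likelihood), which is what the refinement
test does.

## Event-order collapsing

Within-individual episode ranks above `k_max` (default 5) are collapsed
into the top stratum: high-order strata are rare (a fraction of a percent
of individuals in registry data), and one parameter per (interval, order)
cell makes sparse strata a convergence hazard. The uncollapsed rank is kept
in `original_rank`; collapsed episodes share the stratum-`k_max` baseline
and are never dropped.

## Synthetic cohorts

`simulate_cohort` is the generative twin of the CFPM: per individual, draw
covariates and a gamma frailty, then sample gap times sequentially from the
piecewise-constant hazard `u * lambda_jk * exp(x'beta)` by inverting the
cumulative hazard, ceiling to whole days (>= 1). Follow-up is limited by an
administrative horizon (`followup_days`, the clean type-I censoring used in
all recovery studies) and optionally by a per-episode probability of loss to
follow-up, which marks the drawn end day as censored — a pragmatic stand-in
for retirement/death/emigration whose timing is not modelled. Covariates
are drawn independently of the frailty (no confounding by default).

What the simulator does *not* emulate: calendar-time effects and
seasonality, diagnosis-specific duration shapes, time-varying covariates,
informative censoring, and between-episode at-work gaps (episodes abut each
other within the follow-up window). Passing recovery tests therefore shows
the estimator is correct under its own assumptions, not that those
assumptions hold in any particular registry.

Two packaged scenario files illustrate the two qualitative regimes:
`mental_disorders_like.yaml` (event-dependence dominant: baselines rising
steeply with order, mild frailty) and `neoplasms_like.yaml` (heterogeneity
dominant: strong frailty, near order-constant baselines). Their parameters
are invented, illustrative study conditions.

### Validation study sizes

The replicated recovery study uses 50 replicates of n = 2,000 individuals
(theta 0.5, binary covariate HR 0.8, order-2 baseline 1.5x order-1,
per-day order-1 rate 0.02, 150-day follow-up, fitted on a 90-day grid) —
large enough that the Monte-Carlo standard error of the mean log-HR is
~0.004 while the whole study still runs in seconds per replicate. The
Cox-limit check uses one cohort of 300 individuals at elevated rates so that
1-day cells stay populated. The CI-coverage check uses 40 replicates of 150
individuals under the null.

## Comparison metrics

`%RB` and `%RW` follow the definitions above; both are scale-equivariant
and zero at equality. Printed tables round at one decimal, so the package
reports both the raw value and a round-half-away-from-zero one-decimal
value. Reference-category rows (HR fixed at 1, no CI) are excluded. The
packaged transcriptions of the published hazard-ratio tables reproduce the
published comparison tables cell-for-cell at +-0.1 except for three cells
(all %RW of the Cox reference columns) whose printed values are
inconsistent with the printed intervals they derive from; the test suite
flags rather than hides them.

## Known limitations

* Day-count discretisation of continuous gap times attenuates estimates
  slightly; in the recovery study the mean `theta` estimate is ~0.45 for a
  truth of 0.5 and the mean HR ~0.807 for 0.8. The effect shrinks with
  longer durations and finer grids.
* No empirical-Bayes prediction of individual frailties (only `theta` is
  reported), no left truncation, no competing risks, no time-varying
  covariates, gamma frailty only.
* The Cox-based reference models (CFM/CM/FM) are not user-facing fitters;
  their estimates enter only as external reference tables, and a small
  partial-likelihood oracle exists in the test suite solely to validate the
  Poisson-Cox limit.
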