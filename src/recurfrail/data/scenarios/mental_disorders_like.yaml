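# Illustrative "event-dependence-dominant" scenario: the daily hazard of
# returning to work rises steeply with event order (repeat spells resolve
# faster), while unmeasured heterogeneity is mild.  Parameters are invented
# study conditions for testing, not estimates of any registry.
n_individuals: 2000
grid_cuts: [0, 90, 180, 270]
# rows: intervals (0,90], (90,180], (180,270], (270,inf); columns: event order 1..5
baseline_rates:
  - [0.018, 0.027, 0.036, 0.045, 0.054]
  - [0.012, 0.018, 0.024, 0.030, 0.036]
  - [0.010, 0.015, 0.020, 0.025, 0.030]
  - [0.008, 0.012, 0.016, 0.020, 0.024]
theta: 0.15
max_episodes: 8
k_max: 5
followup_days: 365
censor_prob: 0.03
covariates:
  sex: {Male: 0.5, Female: 0.5}
  age_group: {"16-28": 0.3, "29-35": 0.3, "36-45": 0.25, ">45": 0.15}
beta:
  sex: {Female: -0.09}
  age_group: {"29-35": -0.17, "36-45": -0.27, ">45": -0.46}
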