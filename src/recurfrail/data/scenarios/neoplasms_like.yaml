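# Illustrative "heterogeneity-dominant" scenario: strong gamma frailty
# (some workers recover much faster than others at every spell) with a
# nearly order-constant baseline, and long spells with a declining daily
# hazard.  Parameters are invented study conditions for testing, not
# estimates of any registry.
n_individuals: 2000
grid_cuts: [0, 90, 180, 270]
baseline_rates:
  - [0.016, 0.017]
  - [0.010, 0.011]
  - [0.008, 0.008]
  - [0.006, 0.006]
theta: 1.0
max_episodes: 8
k_max: 5
followup_days: 365
censor_prob: 0.03
covariates:
  sex: {Male: 0.5, Female: 0.5}
  age_group: {"16-28": 0.3, "29-35": 0.3, "36-45": 0.25, ">45": 0.15}
beta:
  sex: {Female: -0.09}
  age_group: {"29-35": -0.27, "36-45": -0.6, ">45": -1.17}
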