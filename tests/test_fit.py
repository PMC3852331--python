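"""Model fitting: recovery, nesting, invariances, prediction."""

import numpy as np
import pandas as pd
import pytest

from recurfrail import (CFPM, CPM, FPM, IntervalGrid, ModelSpec, build_design,
                        expand_cohort, fit, grid_from_durations,
                        predict_episode_hazard, simulate_cohort)
from recurfrail.episodes import ValidationError

from conftest import two_order_config


@pytest.fixture(scope="module")
def fitted(small_cohort):
    cohort, truth = small_cohort
    grid = grid_from_durations(cohort.episodes["duration_days"], 90)
    pp = expand_cohort(cohort, grid)
    results = {name: fit(pp, spec, cohort.schema, grid=grid)
               for name, spec in [("cpm", CPM), ("fpm", FPM), ("cfpm", CFPM)]}
    return cohort, truth, pp, results


def test_contrast_columns_follow_schema():
    # the full registry covariate set: 2+4+7+11+2+2 levels -> 22 contrasts
    schema = {
        "sex": ["Male", "Female"],
        "age_group": ["16-28", "29-35", "36-45", ">45"],
        "health_region": [f"r{i}" for i in range(7)],
        "activity_branch": [f"b{i}" for i in range(11)],
        "regime": ["Salaried", "Self-employed"],
        "entity": ["INSS", "Insurance company"],
    }
    rng = np.random.default_rng(0)
    rows = []
    for i in range(50):
        row = {"individual_id": i, "order_k": 1, "interval_j": 1,
               "exposure_days": 10, "event": int(rng.integers(0, 2))}
        row.update({c: levels[rng.integers(0, len(levels))]
                    for c, levels in schema.items()})
        rows.append(row)
    rows[0]["event"] = 1
    design = build_design(pd.DataFrame(rows), CPM, schema)
    assert design.n_contrasts == 22
    assert ("sex", "Female") in design.contrasts
    assert ("sex", "Male") not in design.contrasts      # reference level


def test_baseline_cell_indexing_stratified_vs_shared():
    df = pd.DataFrame([{"individual_id": 0, "order_k": 3, "interval_j": 2,
                        "exposure_days": 7, "event": 1, "g": "1"}])
    schema = {"g": ["0", "1"]}
    assert build_design(df, CPM, schema).cells == [(2, 3)]
    assert build_design(df, FPM, schema).cells == [(2,)]


def test_unknown_covariate_level_rejected():
    df = pd.DataFrame([{"individual_id": 0, "order_k": 1, "interval_j": 1,
                        "exposure_days": 7, "event": 1, "g": "weird"}])
    with pytest.raises(ValidationError, match="weird"):
        build_design(df, CPM, {"g": ["0", "1"]})


def test_zero_event_cells_are_pinned_with_warning():
    df = pd.DataFrame([
        {"individual_id": 0, "order_k": 1, "interval_j": 1,
         "exposure_days": 7, "event": 1},
        {"individual_id": 0, "order_k": 2, "interval_j": 1,
         "exposure_days": 9, "event": 0},
    ])
    with pytest.warns(RuntimeWarning, match="pinned"):
        design = build_design(df, CPM, {})
    assert design.pinned_cells == [(1, 2)]
    res = fit(df, CPM, {})
    pinned = res.baseline[res.baseline["pinned"]]
    assert list(pinned["interval_j"]) == [1]
    with pytest.raises(ValidationError, match="unidentified"):
        predict_episode_hazard(res, {}, order_k=2, interval_j=1)


def test_loglikelihood_nesting(fitted):
    """The full model can never fit worse than either reduced model."""
    _, _, _, r = fitted
    tol = 1e-4
    assert r["cfpm"].log_likelihood >= r["cpm"].log_likelihood - tol
    assert r["cfpm"].log_likelihood >= r["fpm"].log_likelihood - tol


def test_hazard_ratio_cis_bracket_estimates(fitted):
    _, _, _, results = fitted
    for res in results.values():
        p = res.params
        assert ((p["ci_low"] <= p["hr"]) & (p["hr"] <= p["ci_high"])).all()
        assert (p[["hr", "ci_low", "ci_high"]] > 0).all().all()
        assert res.theta >= 0


def test_record_order_invariance(fitted):
    cohort, _, pp, results = fitted
    shuffled = pp.sample(frac=1.0, random_state=123).reset_index(drop=True)
    res = fit(shuffled, CFPM, cohort.schema)
    ref = results["cfpm"]
    assert res.params["estimate"].to_numpy() == \
        pytest.approx(ref.params["estimate"].to_numpy(), abs=1e-6)
    assert res.theta == pytest.approx(ref.theta, rel=1e-4)
    assert res.log_likelihood == pytest.approx(ref.log_likelihood, abs=1e-6)


def test_cfpm_recovers_generating_parameters(fitted):
    """Point estimates land near the truth on a single medium cohort."""
    cohort, truth, pp, results = fitted
    res = results["cfpm"]
    beta_hat = res.params["estimate"].iloc[0]
    se = res.params["se"].iloc[0]
    assert beta_hat == pytest.approx(np.log(0.8), abs=3.5 * se)
    assert res.theta == pytest.approx(0.5, abs=0.25)
    # order-2 baseline sits ~log(1.5) above order-1 in matching intervals
    base = res.baseline[~res.baseline["pinned"]]
    b1 = base[(base.interval_j == 1) & (base.order_k == 1)]["log_hazard"].iloc[0]
    b2 = base[(base.interval_j == 1) & (base.order_k == 2)]["log_hazard"].iloc[0]
    assert b2 - b1 == pytest.approx(np.log(1.5), abs=0.2)


def test_cpm_estimates_attenuate_under_ignored_frailty(fitted):
    """Ignoring heterogeneity biases the covariate effect toward the null."""
    _, _, _, results = fitted
    hr_cpm = results["cpm"].params["hr"].iloc[0]
    hr_cfpm = results["cfpm"].params["hr"].iloc[0]
    assert abs(np.log(hr_cpm)) < abs(np.log(hr_cfpm))


def test_predict_episode_hazard_proportionality(fitted):
    cohort, _, _, results = fitted
    res = results["cfpm"]
    base = res.baseline[~res.baseline["pinned"]].iloc[0]
    j, k = int(base["interval_j"]), int(base["order_k"])
    h_ref = predict_episode_hazard(res, {"group": "a"}, order_k=k, interval_j=j)
    assert h_ref == pytest.approx(np.exp(base["log_hazard"]))
    h_b = predict_episode_hazard(res, {"group": "b"}, order_k=k, interval_j=j)
    assert h_b / h_ref == pytest.approx(res.params["hr"].iloc[0])
    with pytest.raises(ValidationError):
        predict_episode_hazard(res, {"group": "a"}, order_k=9, interval_j=1)


def test_refined_grid_never_fits_worse(small_cohort):
    """Adding cut points nests the coarser model.  Comparable across grids is
    the survival log-likelihood, i.e. the Poisson one net of its layout-
    dependent offset term sum(d * log n)."""
    cohort, _ = small_cohort
    coarse_grid = IntervalGrid((0, 90))
    fine_grid = IntervalGrid((0, 30, 60, 90, 120))
    ll = {}
    for name, grid in [("coarse", coarse_grid), ("fine", fine_grid)]:
        pp = expand_cohort(cohort, grid)
        offset_term = float((pp["event"] * np.log(pp["exposure_days"])).sum())
        ll[name] = fit(pp, CPM, cohort.schema).log_likelihood - offset_term
    assert ll["fine"] >= ll["coarse"] - 1e-6


def test_no_event_table_rejected():
    df = pd.DataFrame([{"individual_id": 0, "order_k": 1, "interval_j": 1,
                        "exposure_days": 7, "event": 0}])
    with pytest.raises(ValidationError):
        fit(df, CPM, {})


def test_confidence_interval_coverage_under_the_null():
    """~95% of 95% CIs cover HR=1 when there is no covariate effect."""
    reps, covered = 40, 0
    for r in range(reps):
        cohort, _ = simulate_cohort(
            two_order_config(n_individuals=150, theta=0.0, hr=1.0), seed=1000 + r)
        pp = expand_cohort(cohort, grid_from_durations(
            cohort.episodes["duration_days"], 90))
        res = fit(pp, CPM, cohort.schema)
        lo, hi = res.params["ci_low"].iloc[0], res.params["ci_high"].iloc[0]
        covered += lo <= 1.0 <= hi
    assert covered / reps >= 0.85
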