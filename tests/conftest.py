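import numpy as np
import pytest
from hypothesis import settings

from recurfrail import IntervalGrid, SimulationConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def two_order_config(n_individuals=400, theta=0.5, hr=0.8, followup=150,
                     rate1=0.02, order2_factor=1.5):
    """Constant-in-gap-time hazard per event order, binary covariate."""
    return SimulationConfig(
        n_individuals=n_individuals,
        grid=IntervalGrid((0,)),
        baseline_rates=np.array([[rate1, rate1 * order2_factor]]),
        beta={"group": {"b": float(np.log(hr))}},
        covariate_probs={"group": {"a": 0.5, "b": 0.5}},
        theta=theta,
        max_episodes=8,
        followup_days=followup,
        k_max=2,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest heterogeneous cohort shared by fit-level tests."""
    cohort, truth = simulate_cohort(two_order_config(n_individuals=400), seed=11)
    return cohort, truth
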