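import pytest
from hypothesis import HealthCheck, settings

import vmrdrift as v
from vmrdrift.config import RunConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """Full study-size cohort (4 conditions x 13 participants), fixed seed."""
    trials, _, traits = v.simulate_cohort(seed=1)
    return trials, traits


@pytest.fixture
def small_cfg():
    """A shrunk schedule for fast structural tests."""
    return RunConfig(
        n_per_condition=2,
        familiarization_trials=8,
        baseline_trials=16,
        pre_strategy_trials=2,
        adaptation_trials=40,
        no_feedback_trials=4,
        washout_trials=24,
    )
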