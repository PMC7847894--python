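import pytest
from hypothesis import HealthCheck, settings

from edamame.quality_index import score_dataset
from edamame.synthetic_data import TrialConfig, simulate_trial

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial, shared read-only across tests."""
    return simulate_trial(seed=0)


@pytest.fixture(scope="session")
def scored_trial(default_trial):
    scored, _ = score_dataset(default_trial.records)
    return scored


@pytest.fixture(scope="session")
def noiseless_trial():
    """Trait noise switched off: trajectories are the pure mean curves."""
    cfg = TrialConfig(hpw_noise_sd=0.0, hue_noise_sd=0.0)
    return simulate_trial(cfg, seed=0)
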