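import pytest

from akicohort.config import RunConfig
from akicohort.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulated cohort shared across read-only tests."""
    return generate_cohort(SimulationConfig(seed=42, n_total=400))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise- and dropout-free cohort: observed data equal the latent truth."""
    cfg = SimulationConfig(
        seed=42,
        n_total=400,
        measurement_cv=0.0,
        dropout_1mo={"observation": 0.0, "intervention": 0.0},
        late_dropout=0.0,
    )
    return generate_cohort(cfg)
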