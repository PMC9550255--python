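import pytest
from hypothesis import settings

from bloodclock import ClockHyperparams, SyntheticConfig, generate_cohort
from bloodclock.schema import default_schema

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_participants=600, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config, schema):
    cohort, truth = generate_cohort(small_config, schema)
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_hp():
    """A small, fast network for functional tests."""
    return ClockHyperparams(
        n_hidden_layers=2,
        units_per_layer=32,
        dropout_rate=0.1,
        max_epochs=80,
        patience=10,
        learning_rate=3e-3,
        batch_size=64,
    )
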