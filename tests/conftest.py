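import pytest

from hillcalf.muscle_model import load_fixture, fixture_names
from hillcalf.synthetic_experiments import (
    NoiseModel,
    generate_clean_experiment_set,
    generate_history_set,
)


@pytest.fixture(scope="session")
def muscles():
    """The three packaged rabbit calf muscle parameter records."""
    return {name: load_fixture(name) for name in fixture_names()}


@pytest.fixture(scope="session")
def clean_sets(muscles):
    """Noise-free synthetic experiment sets, one per muscle (memoized)."""
    return {name: generate_clean_experiment_set(p) for name, p in muscles.items()}


@pytest.fixture(scope="session")
def history_sets(muscles):
    """Noise-free isokinetic ramp/reference sets, one per muscle."""
    return {name: generate_history_set(p, seed=0) for name, p in muscles.items()}


@pytest.fixture
def zero_noise():
    return NoiseModel.zero()
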