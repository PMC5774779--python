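import numpy as np
import pytest

from impres import (
    PopulationConfig,
    TaskParams,
    default_stimulus_set,
    make_study,
)


@pytest.fixture(scope="session")
def stimuli20():
    """The reference 20-prime set: 5 faces per race x age cell."""
    return default_stimulus_set()


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared across tests (12 participants)."""
    return make_study(
        PopulationConfig(n_participants=12, outlier_fraction=0.0),
        TaskParams(),
        rng_seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
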