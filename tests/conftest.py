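import numpy as np
import pytest

from stategrain import SimulationConfig, simulate_subject_betas


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Two-target, few-state configuration on a small grid."""
    return SimulationConfig(
        n_subjects=4,
        grid_shape=(8, 8, 8),
        targets=("self", "far"),
        n_states=5,
        dispersion_by_target={"self": 1.0, "far": 0.2},
        baseline_dispersion=0.3,
        noise_sd=0.2,
        seed=77,
    )


@pytest.fixture
def small_patterns(small_config):
    return simulate_subject_betas(small_config, 0)
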