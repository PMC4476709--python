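import numpy as np
import pytest

from brainsig.core import BrainMask
from brainsig.simulate import (
    SimulationConfig,
    make_ground_truth_pattern,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_mask():
    """Tiny full-grid mask for hand-constructed cases."""
    return BrainMask(inclusion=np.ones((4, 4, 4), dtype=bool))


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(
        grid_shape=(14, 16, 14),
        n_subjects=20,
        effect_size=1.0,
        subject_sd=0.1,
        noise_sd=1.0,
        smooth_fwhm=2.0,
        n_true_regions=4,
        region_size=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """Moderate-SNR emotion dataset with ground truth (20 subjects)."""
    return simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def sim_truth(sim_config):
    return make_ground_truth_pattern(sim_config)
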