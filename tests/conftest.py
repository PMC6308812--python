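import numpy as np
import pytest

from drowsyeeg.synth import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(n_subjects=4, recordings_per_subject=6, seed=11)
    recordings, manifest = simulate_dataset(cfg)
    return cfg, recordings, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
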