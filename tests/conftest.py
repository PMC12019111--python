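import numpy as np
import pytest

from statedyn.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort (default dynamics, fewer subjects) shared across tests."""
    return generate_cohort(GeneratorConfig(n_subjects=4, seed=11))


@pytest.fixture(scope="session")
def mini_config():
    """Config for fast, small-scale generation in individual tests."""
    return GeneratorConfig(n_subjects=2, n_rois=32, n_frames=120, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
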