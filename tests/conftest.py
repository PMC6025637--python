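import numpy as np
import pytest

from actinofam.substitution import jtt_model
from actinofam.synthetic import FamilyConfig, simulate_family


@pytest.fixture(scope="session")
def model():
    """JTT + discrete gamma at the family's divergence settings."""
    return jtt_model(gamma_shape=1.7014, n_categories=8)


@pytest.fixture(scope="session")
def model_k4():
    return jtt_model(gamma_shape=1.7014, n_categories=4)


@pytest.fixture(scope="session")
def model_uniform():
    """Rate-homogeneous JTT (no gamma)."""
    return jtt_model(gamma_shape=None, n_categories=1)


@pytest.fixture(scope="session")
def small_family():
    """A 12-leaf synthetic family with ground truth (session-cached)."""
    cfg = FamilyConfig(n_leaves=12, tree_height=0.05, seed=7)
    proteins, cdnas, truth = simulate_family(cfg)
    return cfg, proteins, cdnas, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
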