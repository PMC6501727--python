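import numpy as np
import pytest

from glsdbn import SyntheticSpec, TrainConfig, generate_group_features


@pytest.fixture(scope="session")
def small_cohort():
    """Fast two-class cohort with planted group structure (60 x 40)."""
    spec = SyntheticSpec(
        n_per_class=30, n_features=40, n_groups=5, n_active_groups=2, seed=7
    )
    fm, truth = generate_group_features(spec)
    return fm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def fast_train_config():
    return TrainConfig(epochs=5, seed=3)
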