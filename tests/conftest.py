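import numpy as np
import pytest

from lrbsf import SyntheticSpec, make_beta_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_null_table():
    """2-class null beta table on a small grid (no class signal)."""
    spec = SyntheticSpec(
        n_classes=2,
        trials_per_class=20,
        grid_shape=(8, 8, 4),
        effect_size=0.0,
        seed=101,
    )
    return make_beta_table(spec)


@pytest.fixture(scope="session")
def small_separable_table():
    """2-class strongly separable beta table on a small grid."""
    spec = SyntheticSpec(
        n_classes=2,
        trials_per_class=20,
        grid_shape=(8, 8, 4),
        effect_size=(2.0, 8.0),
        noise_sd=0.5,
        seed=202,
    )
    return make_beta_table(spec)
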