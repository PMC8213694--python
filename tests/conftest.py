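import numpy as np
import pytest

from vegcoupling.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 6x6 synthetic dataset with mixed regimes, reused across test modules."""
    cfg = SyntheticConfig(ny=6, nx=6, seed=11, mask_fraction=0.1)
    return generate_dataset(cfg, timescales=[1, 2, 3, 9])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
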