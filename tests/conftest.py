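from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted():
    """Default planted-signal fixture: 59 samples, 125 channels, 5 informative."""
    from ivspec import planted_dataset

    ds, truth = planted_dataset(seed=7)
    return ds, truth


@pytest.fixture(scope="session")
def planted_split(planted):
    from ivspec import kennard_stone_split

    ds, truth = planted
    return kennard_stone_split(ds, 36)


@pytest.fixture(scope="session")
def small_planted():
    """Smaller fixture (50 channels, 5 informative) for per-method unit tests."""
    from ivspec import kennard_stone_split, planted_dataset

    ds, truth = planted_dataset(n_samples=59, n_channels=50, n_informative=5, seed=3)
    split = kennard_stone_split(ds, 36)
    return ds, truth, split
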