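import numpy as np
import pytest

import droughtyield as dy


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest useful world: 2x2 coarse cells, 2 countries, fixed calendar."""
    return dy.SynthConfig(
        n_years=36,
        fine_shape=(12, 12),
        coarse_factor=6,
        n_countries=2,
        seed=11,
        fixed_calendar=(4, 8),
        force_wrap_case=False,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    return dy.generate_world(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_spei(tiny_world):
    return dy.compute_spei(tiny_world.ppet.values, tiny_world.config.n_years)
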