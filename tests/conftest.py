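import numpy as np
import pytest

from blurmoe.synthetic import SyntheticConfig, generate_cohort, generate_tile


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def textured_tiles(default_config):
    """A small pool of default synthetic tiles (both classes)."""
    rng = np.random.default_rng(123)
    return [
        generate_tile(int(rng.integers(0, 2)), default_config, rng)
        for _ in range(40)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A compact labelled cohort reused by expert/MoE tests."""
    cfg = SyntheticConfig(n_patients=60, tiles_per_slide=12, seed=9)
    return generate_cohort(cfg)
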