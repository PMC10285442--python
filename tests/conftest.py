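import numpy as np
import pytest

from spiderfear import BrainSpec, EffectConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> EffectConfig:
    return EffectConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def small_spec() -> BrainSpec:
    """Tiny 6x6x6 brain with a 2x2x2 planted region, for fast GLM tests."""
    roi = tuple((x, y, z) for x in (2, 3) for y in (2, 3) for z in (2, 3))
    return BrainSpec(grid_dims=(6, 6, 6), true_roi=roi)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
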