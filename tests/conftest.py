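import numpy as np
import pytest

from eggchem import (
    GeneratorConfig,
    default_distributions,
    default_panel,
    generate_profiles,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def dists():
    return default_distributions()


@pytest.fixture(scope="session")
def table249():
    """Default-size synthetic table (127 + 122), fixed seed."""
    return generate_profiles(cfg=GeneratorConfig(seed=11))


@pytest.fixture()
def small_table():
    """Small table (8 + 8) for fast structural tests."""
    cfg = GeneratorConfig(
        n_per_class={"free-range": 8, "caged": 8}, seed=42
    )
    return generate_profiles(cfg=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
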