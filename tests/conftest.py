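import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from fibersr.bundle import FiberBundleLayout, generate_layout, precompute_masks
from fibersr.pipeline import make_fixtures


@pytest.fixture(scope="session")
def small_layout() -> FiberBundleLayout:
    """Default-geometry bundle over a 64 px field."""
    return generate_layout(
        pitch=3.3,
        jitter_sd=0.3,
        core_radius_range=(1.5, 2.0),
        field_shape=(64, 64),
        pixel_size=0.316,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_masks(small_layout):
    return precompute_masks(small_layout)


@pytest.fixture(scope="session")
def fixtures():
    """Packaged deterministic test assets (layout, tiles, stack, toy frame)."""
    return make_fixtures(seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
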