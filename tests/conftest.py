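import numpy as np
import pytest

from tubuleseg import PhantomParams, build_model, generate_patch
from tubuleseg.model import SegModelSpec


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Phantom settings scaled to 128 px for fast unit tests."""
    return PhantomParams(
        patch_size=128,
        n_tubules_range=(1, 3),
        lumen_radius_range=(10.0, 22.0),
        ring_thickness_range=(4.0, 8.0),
        incomplete_fraction=0.25,
        distractor_count_range=(0, 2),
        empty_fraction=0.0,
        noise_sd=4.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_patch(small_params):
    return generate_patch(small_params)


@pytest.fixture(scope="session")
def tiny_model():
    return build_model(SegModelSpec(backbone="tiny", input_size=64), seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
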