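import numpy as np
import pytest

from actinpick import PhantomParams, build_model_library
from actinpick.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def small_library():
    """15-model library on a 64-px box (same voxel size as production)."""
    return build_model_library(PhantomParams(), n_models=15, box_px=64, voxel_size=4.36)


@pytest.fixture(scope="session")
def library128():
    """Library on a 128-px box, large enough for uncropped 128-px outputs."""
    return build_model_library(PhantomParams(), n_models=3, box_px=128, voxel_size=4.36)


@pytest.fixture(scope="session")
def fixture50():
    """Stratified 50-scene dataset with known per-scene filament kinds."""
    return make_fixture(7, FixtureSpec(n_samples=50, box_px=64))


@pytest.fixture(scope="session")
def fixture20():
    return make_fixture(3, FixtureSpec(n_samples=20, box_px=64))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
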