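import numpy as np
import pytest

from cephalo.core import ImageSpace, LandmarkScheme, LandmarkSet, N_LANDMARKS
from cephalo.synthetic import ShapeModel, make_dataset


@pytest.fixture(scope="session")
def scheme():
    return LandmarkScheme.default()


@pytest.fixture(scope="session")
def space1200():
    return ImageSpace(1200, 1200, mm_per_px=0.35)


@pytest.fixture(scope="session")
def shape_model():
    return ShapeModel.default()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six rendered 64 px images with ground truth (session-cached)."""
    return make_dataset(6, input_side=64, seed=11)


@pytest.fixture
def random_set(scheme, space1200):
    def make(seed=0, role="ground_truth", lo=100.0, hi=1100.0):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(lo, hi, size=(N_LANDMARKS, 2))
        return LandmarkSet(scheme, space1200, coords, role=role)

    return make
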