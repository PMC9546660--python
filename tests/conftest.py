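import numpy as np
import pytest

from oralcad.synth import (
    FeatureFixtureSpec,
    ImageFixtureSpec,
    make_feature_fixture,
    make_image_fixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """One 32x32 random RGB image."""
    return rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def small_images():
    """Tiny two-class synthetic histology image set (no jitter)."""
    return make_image_fixture(ImageFixtureSpec(n_per_class=10, seed=11))


@pytest.fixture(scope="session")
def jittered_images():
    """Two-class image set with staining-variation color jitter."""
    return make_image_fixture(
        ImageFixtureSpec(n_per_class=10, color_jitter=0.15, seed=11)
    )


@pytest.fixture(scope="session")
def planted_features():
    """Feature matrix with 2 informative among 6 noise columns (D=8)."""
    return make_feature_fixture(
        FeatureFixtureSpec(n_samples=100, n_informative=2, n_noise=6, seed=42)
    )


@pytest.fixture(scope="session")
def wide_planted_features():
    """n=200 matrix with 2 informative among 50 noise columns."""
    return make_feature_fixture(FeatureFixtureSpec(seed=7))
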