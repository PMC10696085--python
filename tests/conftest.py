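import numpy as np
import pytest

from musemap import (DegradeSpec, SceneSpec, SyntheticImage,
                     degrade_to_unfixed, generate_ffpe_image)


@pytest.fixture(scope="session")
def ffpe_image() -> SyntheticImage:
    """A small positive FFPE-domain scene shared across tests."""
    return generate_ffpe_image(
        SceneSpec(width=192, height=160, cancer_fraction=0.2, n_glands=1,
                  rng_seed=11))


@pytest.fixture(scope="session")
def negative_image() -> SyntheticImage:
    return generate_ffpe_image(
        SceneSpec(width=192, height=160, cancer_fraction=0.0, n_glands=0,
                  rng_seed=12))


@pytest.fixture(scope="session")
def unfixed_image(ffpe_image) -> SyntheticImage:
    return degrade_to_unfixed(ffpe_image, DegradeSpec(rng_seed=13))


def blank_image(height: int, width: int) -> SyntheticImage:
    """Content-free image for pure geometry checks."""
    return SyntheticImage(
        pixels=np.zeros((height, width, 3), dtype=np.float32),
        domain="ffpe", label="negative",
        mask=np.zeros((height, width), dtype=np.uint8),
        image_id=f"blank-{height}x{width}")
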