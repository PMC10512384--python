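import numpy as np
import pytest

from kspc import Bandwidth, KsPC, VolumetricImage
from kspc.phantom import Blob, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def blob_phantom():
    """Noiseless centered Gaussian blob (sigma 6 mm) on zero background, 64^3."""
    spec = PhantomSpec(
        dims=(64, 64, 64),
        blobs=(Blob(center=(31.5, 31.5, 31.5), sigma=(6.0, 6.0, 6.0), amplitude=8.0),),
        background_level=0.0,
        noise_scale=0.0,
        seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def blob_results(blob_phantom):
    """Fitted KsPC density on the noiseless blob phantom, h = 2 mm."""
    image, _ = blob_phantom
    return KsPC(image, Bandwidth(2.0, 2.0, 2.0)).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_small_image(rng):
    """Random 5^3 integer-SUV volume with anisotropic spacing."""
    values = rng.integers(0, 5, size=(5, 5, 5)).astype(float)
    values[0, 0, 0] = 1.0  # ensure at least one positive voxel
    return VolumetricImage(values=values, spacing=(1.0, 1.0, 1.0))
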