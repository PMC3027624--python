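import numpy as np
import pytest

from enhancevol.phantom import generate, scenario


@pytest.fixture(scope="session")
def rim_baseline():
    """Noiseless cavity-with-enhancing-rim phantom: (pre, post, truth, atlas)."""
    return generate(scenario("rim_baseline", 0)[0])


@pytest.fixture()
def simple_volume():
    """Small random integer-valued volume on a 1 mm isotropic grid."""
    from enhancevol.volume_io import ImageVolume

    rng = np.random.default_rng(42)
    data = rng.integers(0, 500, (20, 18, 9)).astype(float)
    affine = np.eye(4)
    affine[:3, 3] = (-10.0, -9.0, -4.0)
    return ImageVolume(data, (1.0, 1.0, 1.0), affine)
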