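import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from aptw.io import OffsetTable
from aptw.phantom import (
    B0FieldSpec,
    PhantomSpec,
    PoolParameterSet,
    SaturationSpec,
    build_phantom,
)


@pytest.fixture(scope="session")
def sat():
    return SaturationSpec()


@pytest.fixture(scope="session")
def tissue_pools():
    return PoolParameterSet.brain_tissue()


@pytest.fixture(scope="session")
def default_table():
    return OffsetTable.default_protocol()


@pytest.fixture(scope="session")
def b0_phantom():
    """Noise-free 64x64 phantom with a +/-0.3 ppm smooth B0 field."""
    return build_phantom(PhantomSpec(b0=B0FieldSpec(amplitude_ppm=0.3)))


@pytest.fixture(scope="session")
def flat_phantom():
    """Noise-free 64x64 phantom with no B0 field and no motion."""
    return build_phantom(PhantomSpec(b0=None))


@pytest.fixture(scope="session")
def smooth_image():
    """Bandlimited test image with texture: gradients everywhere."""
    rng = np.random.default_rng(7)
    h = w = 64
    rr, cc = np.mgrid[0:h, 0:w]
    radial = ((rr - 31.5) ** 2 + (cc - 31.5) ** 2) / (2 * 32.0**2)
    tex = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    return 1000.0 * (1.0 - 0.4 * radial) * (1.0 + 0.4 * tex / np.abs(tex).max())
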