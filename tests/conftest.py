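import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from lamellakit.simulator import InstrumentState, SimulatedDriver, VirtualSpecimen


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def smooth_image():
    """Stripe-free smooth random field in [0, 1], 256 x 320."""
    r = np.random.default_rng(0)
    img = gaussian_filter(r.normal(0, 1, (256, 320)), 3)
    return (img - img.min()) / np.ptp(img)


def textured_specimen(seed=4, shape=(40, 400, 400), voxel_nm=50.0):
    """Uniform block with bright near-surface inclusions for realignment."""
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[:nz, :ny, :nx]
    labs = np.ones(shape, np.uint8)
    r = np.random.default_rng(seed)
    margin = min(20, ny // 3, nx // 3)
    for _ in range(40):
        cy = r.integers(margin, ny - margin)
        cx = r.integers(margin, nx - margin)
        rad = r.integers(3, 9)
        labs[((zz - 2) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) < rad ** 2] = 2
    return VirtualSpecimen(labs, voxel_nm, {1: 0.5, 2: 0.5}, {1: 100.0, 2: 200.0})


@pytest.fixture
def specimen():
    return textured_specimen()


def make_driver(specimen=None, seed=5, drift=(0.0, 0.0), current_offsets=None,
                noise_scale=0.05):
    spec = specimen if specimen is not None else textured_specimen()
    state = InstrumentState(seed=seed, drift_nm_per_min=np.asarray(drift, float),
                            current_offsets_um=current_offsets or {})
    return SimulatedDriver(spec, state, noise_scale=noise_scale)
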