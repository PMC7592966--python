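import numpy as np
import pytest
from scipy import ndimage

from hepaseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_case():
    """One default-sized phantom shared across tests (deterministic)."""
    return generate_phantom(PhantomSpec(seed=5))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, fast phantom for I/O and pipeline plumbing tests."""
    spec = PhantomSpec(shape=(64, 64, 32), spacing=(1.0, 1.0, 2.0),
                       tumor_count=1, tumor_radius_range=(4.0, 6.0), seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def two_phase_disk():
    """Noisy two-phase disk: truth, image, and the generating parameters.

    128x128, disk radius 30 at the center, inside 0.3 / outside 0.7,
    additive Gaussian noise sigma = 0.05, fixed seed.
    """
    rng = np.random.default_rng(42)
    yy, xx = np.mgrid[:128, :128]
    truth = (yy - 64) ** 2 + (xx - 64) ** 2 <= 30**2
    img = np.where(truth, 0.3, 0.7) + rng.normal(0, 0.05, (128, 128))
    return {"truth": truth, "img": img, "inside": 0.3, "outside": 0.7, "sigma": 0.05}


@pytest.fixture(scope="session")
def two_phase_volume():
    """3D two-phase step volume with noise for diffusion-filter tests."""
    rng = np.random.default_rng(11)
    shape = (64, 64, 32)
    z = np.mgrid[: shape[0], : shape[1], : shape[2]][0]
    phase = z >= 32
    img = np.where(phase, 0.7, 0.3) + rng.normal(0, 0.05, shape)
    core_a = ndimage.binary_erosion(~phase, iterations=3)
    core_b = ndimage.binary_erosion(phase, iterations=3)
    return {"img": img.astype(np.float32), "phase": phase,
            "core_a": core_a, "core_b": core_b}
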