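import numpy as np
import pytest

from ltem_restore.image_model import Image
from ltem_restore import synthetic
from ltem_restore.synthetic import BlurFieldSpec, NoiseModel, make_kernel_field, degrade, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """128px vesicle/micelle/dot scene with its clean phantom."""
    scene = synthetic.standard_scene(128, seed=1)
    return scene, make_phantom(scene)


@pytest.fixture(scope="session")
def noisy_small_scene(small_scene):
    """Standard mixed-noise degradation of the 128px scene (no blur)."""
    scene, clean = small_scene
    delta = make_kernel_field(BlurFieldSpec("uniform", 0, 0, 3), scene.image_size, 128, 128)
    noisy = degrade(clean, delta, synthetic.standard_noise(seed=2))
    return clean, noisy


@pytest.fixture(scope="session")
def textured_pair():
    """Random textured 128px patch and its blur by a known 9x9 Gaussian
    (sigma 1.5) embedded in 25x25 support."""
    from scipy.signal import fftconvolve

    gen = np.random.default_rng(0)
    sharp = gen.normal(0.5, 0.15, (128, 128))
    k9 = synthetic._gaussian_kernel(1.5, 9)
    ktrue = np.zeros((25, 25))
    ktrue[8:17, 8:17] = k9
    blurred = fftconvolve(np.pad(sharp, 12, mode="symmetric"), ktrue, mode="valid")
    return sharp, blurred, ktrue
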