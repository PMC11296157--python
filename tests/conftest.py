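import numpy as np
import pytest

from foramcurve.phantom import (
    PhantomParams,
    generate_phantom,
    sphere_shell_params,
)
from foramcurve.stackio import VolumePair


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shell_pair() -> VolumePair:
    """Single-chamber spherical shell, noise-free: analytically tractable."""
    params = sphere_shell_params(r_out=8.0, wall_thickness=2.0, noise_sd=0.0, seed=1)
    return generate_phantom(params, specimen_id="shell")


@pytest.fixture(scope="session")
def spiral_pair() -> VolumePair:
    """Generic asymmetric multi-chamber phantom (all six orientations
    pairwise distinct)."""
    params = PhantomParams(
        n_chambers=4,
        chamber_radius_vox=5.0,
        spiral_growth_rate=1.2,
        trochospire_pitch=1.5,
        wall_thickness_vox=2.0,
        volume_shape=(28, 26, 24),
        noise_sd=800.0,
        seed=7,
    )
    return generate_phantom(params, specimen_id="spiral")


def random_labels(rng: np.random.Generator, shape=(5, 5, 5)) -> np.ndarray:
    return rng.integers(0, 3, size=shape).astype(np.uint8)
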