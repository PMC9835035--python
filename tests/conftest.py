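import numpy as np
import pytest

from dixonsep import ScalarField3D, TissueRegion, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_fields(rng):
    """A pair of random non-negative fields sharing one grid."""
    a = ScalarField3D(rng.uniform(0, 10, (12, 14, 9)))
    b = ScalarField3D(rng.uniform(0, 10, (12, 14, 9)), a.spacing)
    return a, b


@pytest.fixture
def small_phantom():
    """Noise-free two-region phantom: fat shell + water-dominant core."""
    shell = TissueRegion(
        geometry="ellipsoid", center=(15.5, 15.5, 15.5), semi_axes=(14, 13, 14),
        fat_fraction=0.9, intensity=100.0,
    )
    core = TissueRegion(
        geometry="ellipsoid", center=(15.5, 15.5, 15.5), semi_axes=(7, 7, 7),
        fat_fraction=0.1, intensity=110.0,
    )
    spec = PhantomSpec(shape=(32, 32, 32), regions=(shell, core), noise_sigma=0.0, seed=42)
    channels, labels = generate_phantom(spec)
    return spec, channels, labels
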