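import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wtmm_aniso import FieldSpec, ScalarField, generate_field, make_scale_ladder

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=20,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_ladder():
    """Cheap 6-scale ladder for 128-256 px fixtures."""
    return make_scale_ladder(4, 32, 6)


@pytest.fixture(scope="session")
def white_noise_256():
    return generate_field(FieldSpec(256, "white_noise", seed=2))


@pytest.fixture(scope="session")
def stripes_256():
    return generate_field(
        FieldSpec(256, "oriented_stripes", orientation_deg=0.0, wavelength=16, seed=5)
    )


@pytest.fixture(scope="session")
def stripes_256_wide():
    """Oblique grating whose wavelength covers the small_ladder scale range."""
    return generate_field(
        FieldSpec(256, "oriented_stripes", orientation_deg=30.0, wavelength=32, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def constant_field():
    return ScalarField(np.full((128, 128), 3.0))
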