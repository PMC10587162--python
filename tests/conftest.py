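import numpy as np
import pytest

from fetalbiom import LabelSchema, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def schema():
    return LabelSchema()


@pytest.fixture(scope="session")
def small_spec():
    """A compact phantom at 1 mm in-plane spacing for fast unit tests."""
    return PhantomSpec(
        ga_weeks=28.0,
        cerebrum_half_axes_mm=(37.5, 30.0, 31.5),  # CBPD truth 60 mm
        cerebellum_half_axes_mm=(19.5, 15.0, 12.5),  # TCD truth 30 mm
        ventricle_long_mm=(20.0, 20.0),
        ventricle_short_mm=(6.0, 6.0),
        spacing_mm=(3.0, 1.0, 1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
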