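import numpy as np
import pytest

from discsig import PhantomSpec, generate_disc_phantom, nucleus_seed_pixel

SPACING = 320.0 / 512.0


def make_spec(**overrides) -> PhantomSpec:
    """Phantom on a small canvas (same physical resolution) for fast tests."""
    kwargs = dict(
        image_shape=(160, 160),
        pixel_spacing_mm=(SPACING, SPACING),
        disc_center_mm=(50.0, 50.0),
        disc_semi_axes_mm=(22.0, 6.2),
        nucleus_semi_axes_mm=(10.0, 3.5),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def centered_phantom():
    """Noiseless, symmetric, axis-aligned phantom and its truth."""
    spec = make_spec()
    slc, truth = generate_disc_phantom(spec)
    return spec, slc, truth


@pytest.fixture(scope="session")
def gradient_phantom():
    """Noiseless phantom with a positive longitudinal intensity gradient."""
    spec = make_spec(intensity_gradient=0.25)
    slc, truth = generate_disc_phantom(spec)
    return spec, slc, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def seed_of(spec: PhantomSpec):
    return nucleus_seed_pixel(spec)
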