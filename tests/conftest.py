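import numpy as np
import pytest

from conecensus.synthetic import FlatMountSpec, generate_flatmount


@pytest.fixture()
def small_spec():
    """Small, quick flat-mount: ~600 nuclei on a 256^2 image."""
    return FlatMountSpec(
        image_size=(256, 256),
        retina_radius=110.0,
        n_cones_total=600,
        seed=7,
    )


@pytest.fixture()
def small_flatmount(small_spec):
    return generate_flatmount(small_spec)


def gaussian_field(shape, spots, background=0.0):
    """Render exact Gaussians for hand-built detection cases.

    ``spots`` is a list of (x, y, amplitude, sigma).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    for x, y, a, s in spots:
        img += a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * s * s))
    return img
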