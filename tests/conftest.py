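import numpy as np
import pytest
from scipy import ndimage

from stenoscan.phantom import (
    BModeFrame,
    NoiseParams,
    make_phantom_spec,
    render_bmode,
    render_truth,
)

ALL_PRESETS = [
    ("A", "I"), ("A", "II"), ("A", "III"),
    ("B", "I"), ("B", "II"), ("B", "III"),
    ("C", "I"), ("C", "II"), ("C", "III"),
]


@pytest.fixture(scope="session")
def noise_free():
    """Noise parameters for a clean piecewise-constant rendering."""
    return NoiseParams(speckle_scale=0.0, blur_sigma=0.0)


@pytest.fixture(scope="session")
def center_frame_factory():
    """Render the stenosis-centre frame of a preset phantom."""

    def factory(vessel_type, stenosis_class, noise=None, seed=0):
        spec = make_phantom_spec(vessel_type, stenosis_class)
        truth = render_truth(spec, spec.stenosis_center)
        if noise is None:
            noise = NoiseParams(seed=seed)
        return spec, truth, render_bmode(truth, noise)

    return factory


@pytest.fixture(scope="session")
def disk_frame():
    """A 64x64 blurred bright disk on dark background (radius 20 px)."""
    size = 64
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rr = np.hypot(xx - 31.5, yy - 31.5)
    img = ndimage.gaussian_filter(np.where(rr <= 20, 0.9, 0.1), 1.0)
    return BModeFrame(intensity=img, pixel_spacing=0.1, frame_index=0,
                      axial_position=0.0, theta=0.0)
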