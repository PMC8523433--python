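import math

import numpy as np
import pytest

from conemosaic.detection import ConeSet
from conemosaic.image import RetinalImage


def gaussian_spot_image(centers_px, sigma_px=2.0, amplitude=500.0, shape=(64, 64),
                        pixel_scale_um=1.5, background=0.0):
    """Render Gaussian spots at pixel coordinates (row, col); integer-quantized."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, float(background))
    for (cy, cx) in centers_px:
        img += amplitude * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)))
    return RetinalImage(np.floor(img + 0.5), pixel_scale_um=pixel_scale_um, bit_depth=16)


def triangular_lattice_cones(spacing_um=10.0, region_um=200.0):
    """Exact triangular-lattice coordinates filling [0, region]^2."""
    row_h = spacing_um * math.sqrt(3.0) / 2.0
    pts = []
    i = 0
    while i * row_h <= region_um:
        x0 = spacing_um / 2.0 if i % 2 else 0.0
        x = x0
        while x <= region_um:
            pts.append((x, i * row_h))
            x += spacing_um
        i += 1
    pts = np.asarray(pts)
    return ConeSet(
        x_um=pts[:, 0], y_um=pts[:, 1],
        intensity=np.full(len(pts), np.nan),
        provenance="ground_truth",
    )


@pytest.fixture
def single_spot_image():
    return gaussian_spot_image([(22, 30)])


@pytest.fixture
def lattice_cones():
    return triangular_lattice_cones()


def coord_set(cones, ndigits=6):
    """Hashable coordinate set for exact comparisons of detections."""
    return set(zip(np.round(cones.y_um, ndigits), np.round(cones.x_um, ndigits)))
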