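"""In-memory container for a 2-D grayscale retinal image with physical scale."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np


@dataclass
class RetinalImage:
    """A 2-D intensity grid with a known pixel scale.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (rows = y, columns = x).
    pixel_scale_um
        Micrometers per pixel; 1.5 µm/px is the native scale of the
        high-magnification confocal SLO module.
    bit_depth
        8 or 16; intensities must lie in [0, 2**bit_depth - 1].
    origin_um
        (x, y) of the top-left pixel center in the parent composite image,
        in µm.  (0, 0) for a stand-alone image; set by ROI cropping so
        local coordinates map back to composite coordinates.
    """

    pixels: np.ndarray
    pixel_scale_um: float = 1.5
    bit_depth: int = 16
    origin_um: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not (self.pixel_scale_um > 0):
            raise ValueError("pixel_scale_um must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities outside [0, 2**bit_depth - 1]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def side_um(self) -> Tuple[float, float]:
        """Physical extent (width_um, height_um)."""
        h, w = self.pixels.shape
        return (w * self.pixel_scale_um, h * self.pixel_scale_um)

    def to_local_um(self, x_um: float, y_um: float) -> Tuple[float, float]:
        """Composite µm coordinates → image-local µm coordinates."""
        return (x_um - self.origin_um[0], y_um - self.origin_um[1])

    def to_composite_um(self, x_um: float, y_um: float) -> Tuple[float, float]:
        """Image-local µm coordinates → composite µm coordinates."""
        return (x_um + self.origin_um[0], y_um + self.origin_um[1])
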