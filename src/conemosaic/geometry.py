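"""Retinal geometry: eccentricity scaling, ROI placement, detection radii.

Distances on the retina are expressed in micrometers; positions in an image
are measured from the top-left pixel center (x along columns, y along rows,
0-based), with ``µm = pixel index × pixel scale``.  Visual-angle eccentricity
is converted to retinal distance with a fixed angular scale (291 µm per
degree by default, the conventional emmetropic-eye value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .image import RetinalImage

MERIDIANS = ("superior", "inferior", "temporal", "nasal")

#: Default orientation for a right eye (OD): temporal retina to the image
#: left is the usual fundus-photo convention *mirrored*; here we adopt
#: temporal → +x, nasal → −x, superior → −y (up), inferior → +y (down).
#: A left eye (OS) mirrors the horizontal meridians.
_OD_ORIENTATION: Dict[str, Tuple[float, float]] = {
    "temporal": (1.0, 0.0),
    "nasal": (-1.0, 0.0),
    "superior": (0.0, -1.0),
    "inferior": (0.0, 1.0),
}


@dataclass(frozen=True)
class AngularScale:
    """Retinal distance per degree of visual angle."""

    um_per_degree: float = 291.0

    def __post_init__(self) -> None:
        if not (self.um_per_degree > 0):
            raise ValueError("um_per_degree must be strictly positive")


@dataclass(frozen=True)
class FoveaAnchor:
    """Foveal-center position and eye laterality in composite coordinates.

    ``orientation`` maps each meridian name to a unit direction (dx, dy) in
    image axes.  If omitted it is derived from ``laterality``: the OD default
    maps temporal→+x, nasal→−x, superior→−y, inferior→+y; OS mirrors x.
    """

    x_um: float
    y_um: float
    laterality: str = "OD"
    orientation: Dict[str, Tuple[float, float]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        if self.orientation is None:
            omap = dict(_OD_ORIENTATION)
            if self.laterality == "OS":
                omap = {m: (-dx, dy) if m in ("temporal", "nasal") else (dx, dy)
                        for m, (dx, dy) in omap.items()}
            object.__setattr__(self, "orientation", omap)
        dirs = {tuple(np.sign(v)) for v in self.orientation.values()}
        if len(dirs) != len(self.orientation):
            raise ValueError("orientation must map meridians to distinct axis directions")


@dataclass(frozen=True)
class ROISpec:
    """A square analysis window at a given eccentricity and meridian."""

    eccentricity_deg: float
    meridian: str
    side_um: float = 240.0

    def __post_init__(self) -> None:
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity_deg must be >= 0")
        if not (self.side_um > 0):
            raise ValueError("side_um must be > 0")

    @property
    def area_mm2(self) -> float:
        return (self.side_um / 1000.0) ** 2


@dataclass(frozen=True)
class RadiusTable:
    """Eccentricity → detection-radius lookup.

    The default pairs follow published cone inner-segment diameters:
    2.63, 3.17, 3.55, 3.68 and 3.74 µm at 2, 3, 5, 7 and 9° eccentricity.
    """

    pairs: Tuple[Tuple[float, float], ...] = (
        (2.0, 2.63),
        (3.0, 3.17),
        (5.0, 3.55),
        (7.0, 3.68),
        (9.0, 3.74),
    )

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise ValueError("radius table must not be empty")
        eccs = [e for e, _ in self.pairs]
        radii = [r for _, r in self.pairs]
        if any(b <= a for a, b in zip(eccs, eccs[1:])):
            raise ValueError("eccentricities must be strictly increasing")
        if any(r <= 0 for r in radii):
            raise ValueError("radii must be strictly positive")
        if any(b < a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be non-decreasing")


def deg_to_um(ecc_deg: float, scale: AngularScale = AngularScale()) -> float:
    """Convert visual-angle eccentricity (degrees) to retinal distance (µm)."""
    if ecc_deg < 0:
        raise ValueError("eccentricity must be >= 0")
    return ecc_deg * scale.um_per_degree


def um_to_deg(dist_um: float, scale: AngularScale = AngularScale()) -> float:
    """Inverse of :func:`deg_to_um`."""
    if dist_um < 0:
        raise ValueError("distance must be >= 0")
    return dist_um / scale.um_per_degree


def radius_for_eccentricity(ecc_deg: float, table: RadiusTable = RadiusTable()) -> float:
    """Detection radius (µm) at an eccentricity.

    Exact at tabulated eccentricities, linearly interpolated between
    adjacent tabulated points, and clamped to the endpoint values outside
    the tabulated range.
    """
    if ecc_deg < 0:
        raise ValueError("eccentricity must be >= 0")
    eccs = np.array([e for e, _ in table.pairs])
    radii = np.array([r for _, r in table.pairs])
    return float(np.interp(ecc_deg, eccs, radii))


def roi_center(
    fovea: FoveaAnchor,
    ecc_deg: float,
    meridian: str,
    scale: AngularScale = AngularScale(),
) -> Tuple[float, float]:
    """Center (x_um, y_um) of an ROI at ``ecc_deg`` along ``meridian``."""
    if meridian not in fovea.orientation:
        raise ValueError(f"unknown meridian {meridian!r}; known: {sorted(fovea.orientation)}")
    d = deg_to_um(ecc_deg, scale)
    dx, dy = fovea.orientation[meridian]
    return (fovea.x_um + d * dx, fovea.y_um + d * dy)


def extract_roi(image: RetinalImage, center: Tuple[float, float], spec: ROISpec) -> RetinalImage:
    """Crop a square ROI of side ``spec.side_um`` centered at ``center`` (µm).

    The crop is ``round_half_up(side_um / pixel_scale)`` pixels on a side and
    must lie fully inside the image; an out-of-bounds request raises rather
    than clipping silently.  The crop origin is recorded so ROI-local
    coordinates map back to composite coordinates.
    """
    n_px = int(math.floor(spec.side_um / image.pixel_scale_um + 0.5))
    cx_px = center[0] / image.pixel_scale_um
    cy_px = center[1] / image.pixel_scale_um
    row0 = int(round(cy_px - n_px / 2.0))
    col0 = int(round(cx_px - n_px / 2.0))
    h, w = image.pixels.shape
    if row0 < 0 or col0 < 0 or row0 + n_px > h or col0 + n_px > w:
        raise ValueError(
            f"ROI of {n_px} px at center {center} µm exceeds image bounds {h}x{w} px"
        )
    crop = image.pixels[row0 : row0 + n_px, col0 : col0 + n_px].copy()
    ox = image.origin_um[0] + col0 * image.pixel_scale_um
    oy = image.origin_um[1] + row0 * image.pixel_scale_um
    return RetinalImage(
        pixels=crop,
        pixel_scale_um=image.pixel_scale_um,
        bit_depth=image.bit_depth,
        origin_um=(ox, oy),
    )
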