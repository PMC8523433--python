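"""File formats and run configuration.

Images are plain grayscale TIFF or PNG (8- or 16-bit); cone coordinates
travel as ``x_um,y_um,intensity`` CSV with a JSON sidecar recording the
detection parameters; metric tables are one CSV row per ROI.  All outputs
are in micrometers — pixel-unit outputs are deliberately not offered.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

from .detection import ConeSet, DetectionParams
from .image import RetinalImage

METRICS_COLUMNS = ["subject", "ecc_deg", "meridian", "n_cones", "density", "hex_pct", "icd_um", "nnd_um"]


def read_image(path, pixel_scale_um: Optional[float] = None) -> RetinalImage:
    """Read a grayscale TIFF/PNG as a RetinalImage.

    The pixel scale comes from the argument, from a ``<path>.json`` sidecar
    (key ``pixel_scale_um``), or defaults to 1.5 µm/px.  RGB images and
    unsupported bit depths are rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    elif suffix == ".png":
        with PILImage.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "I;16B"):
                raise ValueError(f"{path}: only grayscale PNG supported, got mode {im.mode!r}")
            arr = np.asarray(im)
    else:
        raise ValueError(f"{path}: unsupported format {suffix!r} (TIFF or PNG)")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    elif arr.dtype == np.int32 and arr.min() >= 0 and arr.max() <= 65535:
        arr = arr.astype(np.uint16)
        bit_depth = 16
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype} (8- or 16-bit grayscale)")

    if pixel_scale_um is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            pixel_scale_um = json.loads(sidecar.read_text()).get("pixel_scale_um")
    if pixel_scale_um is None:
        pixel_scale_um = 1.5
    return RetinalImage(pixels=arr, pixel_scale_um=pixel_scale_um, bit_depth=bit_depth)


def write_image(image: RetinalImage, path) -> None:
    """Write a RetinalImage as TIFF/PNG plus a pixel-scale JSON sidecar."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = image.pixels.astype(dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    elif suffix == ".png":
        PILImage.fromarray(arr).save(path)
    else:
        raise ValueError(f"{path}: unsupported format {suffix!r} (TIFF or PNG)")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_scale_um": image.pixel_scale_um}, indent=2))


def write_cones_csv(cones: ConeSet, path) -> None:
    """Write cone coordinates as CSV with a JSON parameter sidecar."""
    path = Path(path)
    df = pd.DataFrame({"x_um": cones.x_um, "y_um": cones.y_um, "intensity": cones.intensity})
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"provenance": cones.provenance}
    params = cones.meta.get("params")
    if isinstance(params, DetectionParams):
        meta["params"] = dataclasses.asdict(params)
    sidecar.write_text(json.dumps(meta, indent=2))


def read_cones_csv(path, provenance: str = "manual") -> ConeSet:
    """Read a cone-coordinate CSV (columns x_um, y_um, optional intensity)."""
    df = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    inten = df["intensity"].to_numpy() if "intensity" in df.columns else np.full(len(df), np.nan)
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", provenance)
    return ConeSet(
        x_um=df["x_um"].to_numpy(),
        y_um=df["y_um"].to_numpy(),
        intensity=inten,
        provenance=provenance,
    )


@dataclass
class RunConfig:
    """Serializable configuration of an analysis run.

    Every analysis output embeds ``config_hash()`` so results are traceable
    to the exact configuration that produced them.
    """

    pixel_scale_um: float = 1.5
    um_per_degree: float = 291.0
    roi_side_um: float = 240.0
    noise_threshold: float = 1.00
    radius_table: Tuple[Tuple[float, float], ...] = (
        (2.0, 2.63), (3.0, 3.17), (5.0, 3.55), (7.0, 3.68), (9.0, 3.74),
    )
    eccentricities_deg: Tuple[float, ...] = (2.0, 3.0, 5.0, 7.0, 9.0)
    meridians: Tuple[str, ...] = ("superior", "inferior", "temporal", "nasal")
    laterality: str = "OD"
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 0

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=list))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "radius_table" in raw:
            raw["radius_table"] = tuple(tuple(p) for p in raw["radius_table"])
        for key in ("eccentricities_deg", "meridians"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_metrics_table(rows: List[Dict], path) -> pd.DataFrame:
    """Write per-ROI metric rows to CSV in the fixed column order."""
    df = pd.DataFrame(rows)
    cols = [c for c in METRICS_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df = df[cols]
    df.to_csv(path, index=False)
    return df
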