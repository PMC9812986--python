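"""File I/O: images, masks, probability maps, polygon annotations, sidecars.

Conventions:

* masks are single-channel PNGs with values {0, 255}, mapped to {0, 1} in
  memory; any other value is rejected.
* 16-bit TIFF images are scaled to 8 bits as ``round(v * 255 / 65535)``.
* probability maps persist as 16-bit PNG with linear scaling [0,1] -> [0,65535].
* polygon annotations are JSON: either ``{"width", "height", "polygons":
  [[[x, y], ...], ...]}`` or a GeoJSON-style FeatureCollection with an
  ``image_size`` entry.  Rasterisation uses the even-odd rule evaluated at
  pixel centres (pixel (r, c) covers the point (c + 0.5, r + 0.5) in 0-based
  polygon coordinates); overlapping polygons union.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "read_image",
    "read_mask",
    "write_mask",
    "write_probability_map",
    "read_probability_map",
    "read_polygons",
    "rasterize_polygons",
    "write_sidecar",
]


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as HxWx3 uint8 (16-bit inputs are rescaled)."""
    path = Path(path)
    arr = _load_array(path)
    if arr.dtype == np.uint16:
        arr = np.rint(arr.astype(np.float64) * 255.0 / 65535.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected 8- or 16-bit")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: unexpected channel layout {arr.shape}")
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel {0,255} PNG mask as a {0,1} uint8 array."""
    path = Path(path)
    arr = _load_array(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel, got shape {arr.shape}")
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 255}:
        bad = [v for v in values.tolist() if v not in (0, 255)]
        raise ValueError(f"{path}: mask contains non-binary values {bad}; expected {{0, 255}}")
    return (arr > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask).astype(np.uint8) * 255), extension=".png")


def write_probability_map(prob: np.ndarray, path: str | Path) -> None:
    scaled = np.rint(np.clip(prob, 0.0, 1.0) * 65535.0).astype(np.uint16)
    iio.imwrite(Path(path), scaled, extension=".png")


def read_probability_map(path: str | Path) -> np.ndarray:
    arr = _load_array(Path(path))
    if arr.dtype != np.uint16:
        raise ValueError(f"{path}: probability maps are stored as 16-bit PNG")
    return (arr.astype(np.float64) / 65535.0).astype(np.float32)


# ----------------------------------------------------------------- polygons
def _evenodd_fill(polygon: np.ndarray, height: int, width: int) -> np.ndarray:
    """Even-odd (crossing-number) rasterisation at pixel centres."""
    xs = polygon[:, 0]
    ys = polygon[:, 1]
    px = np.arange(width, dtype=np.float64) + 0.5
    py = np.arange(height, dtype=np.float64) + 0.5
    inside = np.zeros((height, width), dtype=bool)
    n = len(polygon)
    cx = px[None, :]
    cy = py[:, None]
    for i in range(n):
        x0, y0 = xs[i], ys[i]
        x1, y1 = xs[(i + 1) % n], ys[(i + 1) % n]
        if y0 == y1:
            continue
        crosses = (y0 <= cy) != (y1 <= cy)
        with np.errstate(invalid="ignore", divide="ignore"):
            x_at = x0 + (cy - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (cx < x_at)
    return inside


def _polygon_self_intersects(polygon: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    try:
        return not Polygon(polygon).is_valid
    except Exception:
        return True


def rasterize_polygons(polygons: list, height: int, width: int) -> np.ndarray:
    """Union of even-odd fills of each polygon over a height x width canvas."""
    mask = np.zeros((height, width), dtype=np.uint8)
    for poly in polygons:
        arr = np.asarray(poly, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
            raise ValueError(f"polygon must be a list of >= 3 (x, y) pairs, got shape {arr.shape}")
        if _polygon_self_intersects(arr):
            warnings.warn("self-intersecting polygon; filling with the even-odd rule", stacklevel=2)
        mask |= _evenodd_fill(arr, height, width)
    return mask


def read_polygons(path: str | Path) -> np.ndarray:
    """Read polygon annotations (JSON/GeoJSON-style) into a binary mask."""
    path = Path(path)
    data = json.loads(path.read_text())
    if "features" in data:  # GeoJSON-style
        dims = data.get("image_size") or data.get("properties", {}).get("image_size")
        if not dims:
            raise ValueError(f"{path}: missing image_size metadata")
        height, width = int(dims["height"]), int(dims["width"])
        polygons = []
        for feat in data["features"]:
            geom = feat.get("geometry", {})
            if geom.get("type") == "Polygon":
                for ring in geom["coordinates"]:
                    polygons.append(ring)
    else:
        if "height" not in data or "width" not in data:
            raise ValueError(f"{path}: missing height/width metadata")
        height, width = int(data["height"]), int(data["width"])
        polygons = data.get("polygons", [])
    return rasterize_polygons(polygons, height, width)


# ----------------------------------------------------------------- sidecars
def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_sidecar(path: str | Path, *, config_hash: str = "", inputs: list[str | Path] = (), extra: dict | None = None) -> None:
    """Provenance JSON written next to every file output."""
    from . import __version__

    meta = {
        "tubuleseg_version": __version__,
        "config_hash": config_hash,
        "input_hashes": {str(p): file_sha256(p) for p in inputs},
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2))
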