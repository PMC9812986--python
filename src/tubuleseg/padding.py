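"""Patch-enhancement padding operators and their inverse crops.

Two enhancement modes for square histology patches:

* **reflection** — the patch is flipped horizontally, vertically and
  diagonally, and the four copies assembled into a 2x2 canvas of twice the
  side length (900 -> 1800).  Structures truncated at the patch edge are
  completed by their own mirror image, and every internal seam is continuous.
* **mirror** — a band of ``margin`` pixels adjacent to each side is reflected
  outward across the edge (without repeating the edge pixel), growing the
  canvas by ``2 * margin`` (900, margin 100 -> 1100).  Corners are filled by
  reflecting about both axes.

Both operators transform an attached binary mask identically, and both are
exactly invertible through :func:`crop_core`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.transform import resize as _sk_resize

from .phantom import AnnotatedPatch

__all__ = ["PaddedPatch", "reflection_pad", "mirror_pad", "crop_core", "resize"]


@dataclass
class PaddedPatch:
    """A padded canvas remembering where the original patch sits inside it."""

    image: np.ndarray
    mask: Optional[np.ndarray]
    mode: str  # "reflection" | "mirror" | "none"
    core_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    original_size: int


def _require_square(patch: AnnotatedPatch) -> int:
    h, w = patch.shape
    if h != w:
        raise ValueError(f"padding requires a square patch, got {h}x{w}")
    return h


def _reflect_canvas(arr: np.ndarray) -> np.ndarray:
    """2x2 quadrant layout: original | left-right flip / top-bottom | both."""
    top = np.concatenate([arr, arr[:, ::-1]], axis=1)
    bottom = np.concatenate([arr[::-1, :], arr[::-1, ::-1]], axis=1)
    return np.concatenate([top, bottom], axis=0)


def reflection_pad(patch: AnnotatedPatch) -> PaddedPatch:
    """Quadruple a square patch into its 2x2 self-mirrored canvas."""
    s = _require_square(patch)
    return PaddedPatch(
        image=_reflect_canvas(patch.image),
        mask=None if patch.mask is None else _reflect_canvas(patch.mask),
        mode="reflection",
        core_box=(0, 0, s, s),
        original_size=s,
    )


def mirror_pad(patch: AnnotatedPatch, margin: int = 100) -> PaddedPatch:
    """Reflect a ``margin``-wide band outward across each edge.

    Uses the reflect convention (edge pixel not repeated); corners are the
    double reflection about both axes, which is what ``numpy.pad`` computes.
    """
    s = _require_square(patch)
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin >= s:
        raise ValueError(f"margin ({margin}) must be smaller than the patch side ({s})")
    if margin == 0:
        image = patch.image.copy()
        mask = None if patch.mask is None else patch.mask.copy()
    else:
        pad_img = ((margin, margin), (margin, margin)) + ((0, 0),) * (patch.image.ndim - 2)
        image = np.pad(patch.image, pad_img, mode="reflect")
        mask = None if patch.mask is None else np.pad(patch.mask, ((margin, margin), (margin, margin)), mode="reflect")
    return PaddedPatch(
        image=image,
        mask=mask,
        mode="mirror",
        core_box=(margin, margin, margin + s, margin + s),
        original_size=s,
    )


def crop_core(padded: PaddedPatch) -> AnnotatedPatch:
    """Recover the original patch (bit-exact) from a padded canvas."""
    if padded.core_box is None:
        raise ValueError("padded patch has no core_box")
    r0, c0, r1, c1 = padded.core_box
    image = padded.image[r0:r1, c0:c1].copy()
    mask = padded.mask[r0:r1, c0:c1].copy() if padded.mask is not None else np.zeros(image.shape[:2], dtype=np.uint8)
    return AnnotatedPatch(image=image, mask=mask)


def resize(image_or_map: np.ndarray, target: int) -> np.ndarray:
    """Resize to ``target`` pixels per side.

    Bilinear interpolation for RGB images and probability maps;
    nearest-neighbour for binary masks (values stay in {0, 1}).
    """
    if target < 1:
        raise ValueError("target size must be >= 1")
    arr = np.asarray(image_or_map)
    if arr.shape[0] == target and arr.shape[1] == target:
        return arr.copy()
    out_shape = (target, target) + arr.shape[2:]
    is_binary_mask = arr.ndim == 2 and arr.dtype in (np.uint8, np.bool_, np.int32, np.int64)
    if is_binary_mask:
        out = _sk_resize(arr, out_shape, order=0, preserve_range=True, anti_aliasing=False)
        return out.astype(arr.dtype)
    out = _sk_resize(arr.astype(np.float64), out_shape, order=1, preserve_range=True, anti_aliasing=False)
    if arr.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return np.clip(out, 0.0, 1.0).astype(np.float32) if arr.ndim == 2 else out.astype(np.float32)
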