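"""Overlap tiling of large images and stitching of per-tile predictions.

A tile plan covers a parent image with an exact grid of ``core`` x ``core``
cells; each *tile* extends its core by a context band of
``overlap_fraction * core`` pixels on every side (25% overlap of a 900 core
gives 1350 tiles).  The parent is conceptually padded by reflection so border
tiles are full-size.  Stitching either lets each tile contribute exactly its
core (``core_crop``) or averages overlapping contributions (``mean``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .phantom import AnnotatedPatch

__all__ = ["TilePlan", "plan_tiles", "extract_tiles", "stitch"]


@dataclass(frozen=True)
class TilePlan:
    """Deterministic tiling geometry, serialisable for provenance."""

    parent_height: int
    parent_width: int
    core: int
    overlap_fraction: float
    overlap: int  # pixels of context per side = overlap_fraction * core
    tile: int  # core + 2 * overlap
    n_rows: int
    n_cols: int
    pad_bottom: int  # grid remainder at bottom/right (beyond the overlap band)
    pad_right: int
    origins: tuple = field(default_factory=tuple)  # (row, col) in padded coords

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def core_box(self, index: int) -> tuple[int, int, int, int]:
        """Half-open core box of tile ``index`` in parent coordinates."""
        i, j = divmod(index, self.n_cols)
        return (i * self.core, j * self.core, (i + 1) * self.core, (j + 1) * self.core)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "parent_height", "parent_width", "core", "overlap_fraction",
            "overlap", "tile", "n_rows", "n_cols", "pad_bottom", "pad_right")}
        d["origins"] = [list(o) for o in self.origins]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TilePlan":
        d = json.loads(text)
        d["origins"] = tuple((int(r), int(c)) for r, c in d["origins"])
        return cls(**d)


def plan_tiles(
    parent_height: int,
    parent_width: int,
    core: int = 900,
    overlap_fraction: float = 0.25,
) -> TilePlan:
    """Plan a row-major grid of overlap tiles covering the parent exactly."""
    if parent_height < 1 or parent_width < 1:
        raise ValueError("parent dimensions must be >= 1")
    if not 0.0 <= overlap_fraction <= 0.5:
        raise ValueError("overlap_fraction must be in [0, 0.5]")
    overlap_f = core * overlap_fraction
    if abs(overlap_f - round(overlap_f)) > 1e-9:
        raise ValueError(
            f"core * overlap_fraction must be integral, got {core} * {overlap_fraction}"
        )
    overlap = int(round(overlap_f))
    tile = core + 2 * overlap
    n_rows = -(-parent_height // core)
    n_cols = -(-parent_width // core)
    pad_bottom = n_rows * core - parent_height
    pad_right = n_cols * core - parent_width
    # padded coords place the first core at (overlap, overlap); a tile's origin
    # is its core origin minus the overlap band, i.e. (i*core, j*core)
    origins = tuple((i * core, j * core) for i in range(n_rows) for j in range(n_cols))
    return TilePlan(
        parent_height=parent_height,
        parent_width=parent_width,
        core=core,
        overlap_fraction=overlap_fraction,
        overlap=overlap,
        tile=tile,
        n_rows=n_rows,
        n_cols=n_cols,
        pad_bottom=pad_bottom,
        pad_right=pad_right,
        origins=origins,
    )


def _reflect_pad_2d(arr: np.ndarray, top: int, bottom: int, left: int, right: int) -> np.ndarray:
    """Reflection padding that tolerates pads wider than the array itself."""
    out = arr
    while top or bottom or left or right:
        h, w = out.shape[:2]
        t, b = min(top, h - 1), min(bottom, h - 1)
        l, r = min(left, w - 1), min(right, w - 1)
        if (t, b, l, r) == (0, 0, 0, 0):  # degenerate 1-pixel dimension
            t, b, l, r = top, bottom, left, right
            pad = ((t, b), (l, r)) + ((0, 0),) * (out.ndim - 2)
            return np.pad(out, pad, mode="edge")
        pad = ((t, b), (l, r)) + ((0, 0),) * (out.ndim - 2)
        out = np.pad(out, pad, mode="reflect")
        top, bottom, left, right = top - t, bottom - b, left - l, right - r
    return out


def _pad_parent(arr: np.ndarray, plan: TilePlan) -> np.ndarray:
    return _reflect_pad_2d(
        arr,
        plan.overlap,
        plan.overlap + plan.pad_bottom,
        plan.overlap,
        plan.overlap + plan.pad_right,
    )


def extract_tiles(parent: AnnotatedPatch, plan: TilePlan) -> list[AnnotatedPatch]:
    """Cut the planned tiles out of the (reflection-padded) parent."""
    if parent.shape != (plan.parent_height, plan.parent_width):
        raise ValueError(
            f"plan is for {plan.parent_height}x{plan.parent_width}, "
            f"parent is {parent.shape[0]}x{parent.shape[1]}"
        )
    image_p = _pad_parent(parent.image, plan)
    mask_p = _pad_parent(parent.mask, plan)
    tiles = []
    for r, c in plan.origins:
        tiles.append(
            AnnotatedPatch(
                image=image_p[r : r + plan.tile, c : c + plan.tile].copy(),
                mask=mask_p[r : r + plan.tile, c : c + plan.tile].copy(),
                origin=(r, c),
            )
        )
    return tiles


def stitch(
    tiles: list[np.ndarray],
    plan: TilePlan,
    blend: str = "core_crop",
) -> np.ndarray:
    """Recombine per-tile probability maps into a parent-sized map.

    ``core_crop``: each tile contributes exactly its core box.
    ``mean``: overlapping tile contributions are averaged per pixel.
    """
    if len(tiles) != plan.n_tiles:
        raise ValueError(f"plan expects {plan.n_tiles} tiles, got {len(tiles)}")
    for t in tiles:
        if t.shape[:2] != (plan.tile, plan.tile):
            raise ValueError(f"tile shape {t.shape[:2]} != planned {(plan.tile, plan.tile)}")
    if blend not in ("core_crop", "mean"):
        raise ValueError(f"unknown blend mode: {blend!r}")

    ov = plan.overlap
    if blend == "core_crop":
        full = np.zeros((plan.n_rows * plan.core, plan.n_cols * plan.core), dtype=np.float32)
        for idx, t in enumerate(tiles):
            r0, c0, r1, c1 = plan.core_box(idx)
            full[r0:r1, c0:c1] = t[ov : ov + plan.core, ov : ov + plan.core]
        return full[: plan.parent_height, : plan.parent_width].copy()

    ph = plan.n_rows * plan.core + 2 * ov
    pw = plan.n_cols * plan.core + 2 * ov
    acc = np.zeros((ph, pw), dtype=np.float64)
    cnt = np.zeros((ph, pw), dtype=np.float64)
    for (r, c), t in zip(plan.origins, tiles):
        acc[r : r + plan.tile, c : c + plan.tile] += t
        cnt[r : r + plan.tile, c : c + plan.tile] += 1.0
    out = (acc / np.maximum(cnt, 1.0)).astype(np.float32)
    return out[ov : ov + plan.parent_height, ov : ov + plan.parent_width].copy()
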