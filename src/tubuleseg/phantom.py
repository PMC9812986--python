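"""Seeded synthetic tubule-phantom generator with pixel-perfect ground truth.

Emulates H&E-stained breast-tissue patches at ~20x: each tubule is an
ellipse-like clear lumen surrounded by a ring of dark epithelial nuclei, on an
eosin-pink stromal background.  Patches also contain lumen-bearing distractors
that must *not* be labelled tubule — vessel-like structures (a lumen enclosed
by a thin endothelial ring) and adipocyte-like structures (white blobs with a
thin membrane, optionally clustered) — so false-positive behaviour of a
segmentation model is testable.

The ground-truth mask is the union of tubule footprints (lumen plus nuclear
ring annulus) clipped to the patch; per-instance geometry is kept alongside the
mask so component-count and support oracles stay exact even under accidental
overlap.  Identical parameters (including seed) produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import disk

__all__ = [
    "PhantomParams",
    "TubuleInstance",
    "Distractor",
    "AnnotatedPatch",
    "generate_patch",
    "generate_dataset",
    "generate_large_image",
]


DEFAULT_PALETTE = {
    "background": (231, 180, 188),  # eosin-stained stroma
    "lumen": (244, 242, 245),
    "nucleus": (82, 46, 120),  # hematoxylin
    "cytoplasm": (202, 152, 186),
    "adipocyte": (246, 246, 248),
    "membrane": (186, 156, 176),
}


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings; defaults emulate 900x900 patches at 20x."""

    patch_size: int = 900
    n_tubules_range: tuple[int, int] = (1, 8)
    lumen_radius_range: tuple[float, float] = (25.0, 70.0)
    ring_thickness_range: tuple[float, float] = (10.0, 24.0)
    incomplete_fraction: float = 0.25
    distractor_count_range: tuple[int, int] = (0, 4)
    stain_palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sd: float = 5.0
    empty_fraction: float = 0.2
    stromal_nucleus_density: float = 6e-5  # scattered stromal nuclei per pixel
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size < 64:
            raise ValueError("patch_size must be >= 64")
        for name in ("n_tubules_range", "lumen_radius_range", "ring_thickness_range", "distractor_count_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy min <= max, got {(lo, hi)}")
        if not 0.0 <= self.incomplete_fraction <= 1.0:
            raise ValueError("incomplete_fraction must be in [0, 1]")
        if not 0.0 <= self.empty_fraction <= 1.0:
            raise ValueError("empty_fraction must be in [0, 1]")
        if self.n_tubules_range[0] < 0 or self.distractor_count_range[0] < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.stromal_nucleus_density < 0:
            raise ValueError("stromal_nucleus_density must be non-negative")


@dataclass(frozen=True)
class TubuleInstance:
    """Geometry of one generated tubule: lumen ellipse + nuclear ring annulus.

    The footprint (what the mask covers) is the rotated ellipse with semi-axes
    ``(a + ring_thickness, b + ring_thickness)``.
    """

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # lumen (a, b)
    angle: float  # radians, rotation of the major axis
    ring_thickness: float

    @property
    def outer_axes(self) -> tuple[float, float]:
        a, b = self.semi_axes
        return (a + self.ring_thickness, b + self.ring_thickness)

    def contains(self, row: float, col: float) -> bool:
        """Point-in-footprint test (used by test oracles as well)."""
        a, b = self.outer_axes
        dr = row - self.center[0]
        dc = col - self.center[1]
        u = dc * np.cos(self.angle) + dr * np.sin(self.angle)
        v = -dc * np.sin(self.angle) + dr * np.cos(self.angle)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "angle": float(self.angle),
            "ring_thickness": float(self.ring_thickness),
        }


@dataclass(frozen=True)
class Distractor:
    kind: str  # "vessel" or "adipocyte"
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnnotatedPatch:
    """An RGB patch with its pixel-aligned binary tubule mask."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    origin: Optional[tuple[int, int]] = None
    tubule_count: int = 0
    instances: list[TubuleInstance] = field(default_factory=list)
    distractors: list[Distractor] = field(default_factory=list)

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def sidecar(self) -> dict:
        return {
            "tubule_count": self.tubule_count,
            "origin": list(self.origin) if self.origin is not None else None,
            "instances": [t.to_dict() for t in self.instances],
            "distractors": [d.to_dict() for d in self.distractors],
        }


# ----------------------------------------------------------------- rendering
def _ellipse_support(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    """Boolean raster of a rotated filled ellipse, evaluated at pixel centres."""
    a, b = semi_axes
    cr, cc = center
    extent = max(a, b)
    r0 = max(int(np.floor(cr - extent)) - 1, 0)
    r1 = min(int(np.ceil(cr + extent)) + 2, shape[0])
    c0 = max(int(np.floor(cc - extent)) - 1, 0)
    c1 = min(int(np.ceil(cc + extent)) + 2, shape[1])
    out = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return out
    rows = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
    cols = np.arange(c0, c1, dtype=np.float64)[None, :] - cc
    u = cols * np.cos(angle) + rows * np.sin(angle)
    v = -cols * np.sin(angle) + rows * np.cos(angle)
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _paint(canvas: np.ndarray, support: np.ndarray, color: tuple[int, int, int]) -> None:
    canvas[support] = np.asarray(color, dtype=np.uint8)


def _draw_tubule(
    canvas: np.ndarray, inst: TubuleInstance, palette: dict, rng: np.random.Generator
) -> None:
    shape = canvas.shape[:2]
    outer = _ellipse_support(shape, inst.center, inst.outer_axes, inst.angle)
    lumen = _ellipse_support(shape, inst.center, inst.semi_axes, inst.angle)
    _paint(canvas, outer & ~lumen, palette["cytoplasm"])
    _paint(canvas, lumen, palette["lumen"])
    # ring of nucleus-coloured discs with jittered centres along the annulus
    a, b = inst.semi_axes
    t = inst.ring_thickness
    nucleus_r = max(t / 2.0, 2.0)
    mid_a, mid_b = a + t / 2.0, b + t / 2.0
    perimeter = np.pi * (3 * (mid_a + mid_b) - np.sqrt((3 * mid_a + mid_b) * (mid_a + 3 * mid_b)))
    n_nuclei = max(int(perimeter / (1.6 * nucleus_r)), 6)
    thetas = np.linspace(0.0, 2 * np.pi, n_nuclei, endpoint=False)
    thetas = thetas + rng.uniform(-0.2, 0.2, size=n_nuclei)
    radial_jitter = rng.uniform(-t / 6.0, t / 6.0, size=n_nuclei)
    cos_a, sin_a = np.cos(inst.angle), np.sin(inst.angle)
    nucleus = np.asarray(palette["nucleus"], dtype=np.float64)
    for theta, dj in zip(thetas, radial_jitter):
        u = (mid_a + dj) * np.cos(theta)
        v = (mid_b + dj) * np.sin(theta)
        col = inst.center[1] + u * cos_a - v * sin_a
        row = inst.center[0] + u * sin_a + v * cos_a
        rr, cc = disk((row, col), nucleus_r, shape=shape)
        shade = np.clip(nucleus + rng.uniform(-18, 18), 0, 255).astype(np.uint8)
        canvas[rr, cc] = shade


def _scatter_nuclei(
    canvas: np.ndarray,
    centers: np.ndarray,
    radius: float,
    palette: dict,
    rng: np.random.Generator,
) -> None:
    shape = canvas.shape[:2]
    nucleus = np.asarray(palette["nucleus"], dtype=np.float64)
    for row, col in centers:
        rr, cc = disk((row, col), radius, shape=shape)
        shade = np.clip(nucleus + rng.uniform(-18, 18), 0, 255).astype(np.uint8)
        canvas[rr, cc] = shade


def _draw_distractor(
    canvas: np.ndarray, d: Distractor, palette: dict, rng: np.random.Generator
) -> None:
    shape = canvas.shape[:2]
    if d.kind == "vessel":
        # lumen enclosed by a thin (<= 2 px) layer of hematoxylin-stained
        # endothelial cells — same stain as tubule nuclei, far thinner ring
        outer = _ellipse_support(shape, d.center, (d.semi_axes[0] + 2.0, d.semi_axes[1] + 2.0), d.angle)
        lumen = _ellipse_support(shape, d.center, d.semi_axes, d.angle)
        nucleus = np.asarray(palette["nucleus"], dtype=np.float64)
        shade = np.clip(nucleus + rng.uniform(-12, 12), 0, 255).astype(np.uint8)
        canvas[outer & ~lumen] = shade
        _paint(canvas, lumen, palette["lumen"])
    else:  # adipocyte: white blob with a thin membrane, lymphocytes nearby
        outer = _ellipse_support(shape, d.center, (d.semi_axes[0] + 1.5, d.semi_axes[1] + 1.5), d.angle)
        fill = _ellipse_support(shape, d.center, d.semi_axes, d.angle)
        _paint(canvas, outer & ~fill, palette["membrane"])
        _paint(canvas, fill, palette["adipocyte"])
        if rng.random() < 0.6:
            n_lymph = int(rng.integers(3, 9))
            theta = rng.uniform(0, 2 * np.pi, n_lymph)
            a, b = d.semi_axes
            lymph_r = max(0.12 * (a + b) / 2.0, 1.5)
            dist = (max(a, b) + 1.5) + rng.uniform(1.0, 2.5 * lymph_r, n_lymph)
            centers = np.stack(
                [d.center[0] + dist * np.sin(theta), d.center[1] + dist * np.cos(theta)], axis=1
            )
            _scatter_nuclei(canvas, centers, lymph_r, palette, rng)


# ----------------------------------------------------------------- placement
def _place_tubules(
    params: PhantomParams,
    height: int,
    width: int,
    n: int,
    rng: np.random.Generator,
) -> list[TubuleInstance]:
    instances: list[TubuleInstance] = []
    for _ in range(n):
        a = rng.uniform(*params.lumen_radius_range)
        b = a * rng.uniform(0.6, 1.0)
        angle = rng.uniform(0.0, np.pi)
        t = rng.uniform(*params.ring_thickness_range)
        outer = max(a, b) + t
        incomplete = rng.random() < params.incomplete_fraction
        for _attempt in range(60):
            if incomplete:
                # centre within one lumen radius of a patch edge; bounding the
                # distance by the minor outer semi-axis (b + t) guarantees the
                # footprint crosses the border whatever the rotation
                edge = rng.integers(0, 4)
                d = rng.uniform(0.0, min(a, b + t))
                along = rng.uniform(0.0, 1.0)
                if edge == 0:
                    center = (d, along * width)
                elif edge == 1:
                    center = (height - 1 - d, along * width)
                elif edge == 2:
                    center = (along * height, d)
                else:
                    center = (along * height, width - 1 - d)
            else:
                lo_r, hi_r = outer, height - outer
                lo_c, hi_c = outer, width - outer
                if lo_r >= hi_r or lo_c >= hi_c:
                    center = (height / 2.0, width / 2.0)
                else:
                    center = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            # bounding-circle separation keeps instances disjoint when possible
            ok = all(
                np.hypot(center[0] - o.center[0], center[1] - o.center[1])
                > outer + max(o.outer_axes) + 2.0
                for o in instances
            )
            if ok:
                break
        instances.append(TubuleInstance(center, (a, b), angle, t))
    return instances


def _place_distractors(
    params: PhantomParams,
    height: int,
    width: int,
    n: int,
    instances: list[TubuleInstance],
    rng: np.random.Generator,
) -> list[Distractor]:
    distractors: list[Distractor] = []
    for _ in range(n):
        kind = "vessel" if rng.random() < 0.5 else "adipocyte"
        base_r = rng.uniform(*params.lumen_radius_range) * (0.5 if kind == "vessel" else 0.8)
        base_r = min(base_r, min(height, width) / 2.0 - 1.0)  # fit small canvases
        cluster = 1 if kind == "vessel" else int(rng.integers(1, 4))
        anchor = None
        for _attempt in range(60):
            center = (rng.uniform(base_r, height - base_r), rng.uniform(base_r, width - base_r))
            clear = all(
                np.hypot(center[0] - t.center[0], center[1] - t.center[1])
                > base_r + max(t.outer_axes) + 4.0
                for t in instances
            )
            if clear:
                anchor = center
                break
        if anchor is None:
            continue  # scene too crowded; fewer distractors is acceptable
        for k in range(cluster):
            a = base_r * rng.uniform(0.7, 1.0)
            b = a * rng.uniform(0.6, 1.0)
            if k == 0:
                center = anchor
            else:
                off = rng.uniform(0.8, 1.4) * 2 * a
                theta = rng.uniform(0, 2 * np.pi)
                center = (anchor[0] + off * np.sin(theta), anchor[1] + off * np.cos(theta))
            distractors.append(Distractor(kind, center, (a, b), rng.uniform(0.0, np.pi)))
    return distractors


# ----------------------------------------------------------------- top level
def _render_scene(
    params: PhantomParams, height: int, width: int, rng: np.random.Generator, n_tubules: int
) -> AnnotatedPatch:
    palette = params.stain_palette
    canvas = np.empty((height, width, 3), dtype=np.uint8)
    canvas[...] = np.asarray(palette["background"], dtype=np.uint8)

    instances = _place_tubules(params, height, width, n_tubules, rng)
    n_distract = int(rng.integers(params.distractor_count_range[0], params.distractor_count_range[1] + 1))
    if height * width > params.patch_size**2:
        n_distract = int(round(n_distract * height * width / params.patch_size**2))
    distractors = _place_distractors(params, height, width, n_distract, instances, rng)

    # scattered stromal nuclei (fibroblasts/lymphocytes): hematoxylin-stained
    # dots outside tubule footprints, so nucleus colour alone never implies
    # tubule membership
    n_stromal = int(round(params.stromal_nucleus_density * height * width))
    if n_stromal:
        mean_t = 0.5 * (params.ring_thickness_range[0] + params.ring_thickness_range[1])
        candidates = rng.uniform(0, [height, width], size=(n_stromal, 2))
        keep = [
            (r, c)
            for r, c in candidates
            if not any(inst.contains(r, c) for inst in instances)
        ]
        _scatter_nuclei(
            canvas, np.asarray(keep).reshape(-1, 2), max(0.45 * mean_t, 1.5), palette, rng
        )

    for d in distractors:
        _draw_distractor(canvas, d, palette, rng)
    mask = np.zeros((height, width), dtype=np.uint8)
    for inst in instances:
        _draw_tubule(canvas, inst, palette, rng)
        mask |= _ellipse_support((height, width), inst.center, inst.outer_axes, inst.angle)

    if params.noise_sd > 0:
        noisy = canvas.astype(np.float64) + rng.normal(0.0, params.noise_sd, canvas.shape)
        canvas = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    return AnnotatedPatch(
        image=canvas,
        mask=mask,
        tubule_count=len(instances),
        instances=instances,
        distractors=distractors,
    )


def _draw_n_tubules(params: PhantomParams, rng: np.random.Generator) -> int:
    if rng.random() < params.empty_fraction:
        return 0
    lo, hi = params.n_tubules_range
    return int(rng.integers(lo, hi + 1))


def generate_patch(params: PhantomParams) -> AnnotatedPatch:
    """Generate one annotated patch of ``patch_size`` squared pixels."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = _draw_n_tubules(params, rng)
    return _render_scene(params, params.patch_size, params.patch_size, rng, n)


def generate_dataset(
    params: PhantomParams, n_train: int, n_val: int, seed: int
) -> tuple[list[AnnotatedPatch], list[AnnotatedPatch]]:
    """Generate disjoint seeded train/validation patch lists."""
    params.validate()
    if n_train < 0 or n_val < 0:
        raise ValueError("dataset sizes must be non-negative")
    train_ss, val_ss = np.random.SeedSequence(seed).spawn(2)

    def make(ss: np.random.SeedSequence, n: int) -> list[AnnotatedPatch]:
        rng = np.random.default_rng(ss)
        out = []
        for _ in range(n):
            k = _draw_n_tubules(params, rng)
            out.append(_render_scene(params, params.patch_size, params.patch_size, rng, k))
        return out

    return make(train_ss, n_train), make(val_ss, n_val)


def generate_large_image(params: PhantomParams, height: int, width: int) -> AnnotatedPatch:
    """Generate a large annotated image (stands in for a cropped WSI region)."""
    params.validate()
    if height < params.patch_size or width < params.patch_size:
        raise ValueError("large image must be at least patch_size in both dimensions")
    rng = np.random.default_rng(params.seed)
    area_ratio = (height * width) / float(params.patch_size**2)
    n = int(round(_draw_n_tubules(params, rng) * area_ratio))
    return _render_scene(params, height, width, rng, n)


def write_patch(patch: AnnotatedPatch, image_path, mask_path, sidecar_path=None, params: PhantomParams | None = None) -> None:
    """Write image + {0,255} mask PNGs and an optional JSON geometry sidecar."""
    import imageio.v3 as iio

    iio.imwrite(image_path, patch.image, extension=".png")
    iio.imwrite(mask_path, (patch.mask * 255).astype(np.uint8), extension=".png")
    if sidecar_path is not None:
        meta = patch.sidecar()
        if params is not None:
            p = dataclasses.asdict(params)
            p["stain_palette"] = {k: list(v) for k, v in params.stain_palette.items()}
            meta["params"] = p
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
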