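"""Training loop: augmentation menu, Adam + binary cross entropy, step LR
schedule, early stopping and best-checkpoint selection.

The augmentation menu mirrors the twelve transforms commonly used for
histology patches (shift/scale/rotate, elastic, grid and optical distortion,
gamma, brightness, RGB shift, hue/saturation/value, colour jitter, defocus,
motion and Gaussian blur).  Geometric transforms are applied identically to
image and mask (nearest-neighbour for the mask, so it stays binary);
photometric and blur transforms touch the image only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import draw as skdraw
from skimage import transform as sktransform

from . import nn
from .nn import functional as F
from .model import SegmentationModel
from .padding import mirror_pad, reflection_pad, resize
from .phantom import AnnotatedPatch
from .evaluation import binarize, score

__all__ = ["TrainConfig", "TrainLog", "EpochRecord", "augment", "fit", "AUGMENTATIONS"]


# ============================================================= augmentations
def _warp_pair(image, mask, inverse_map):
    """Apply one inverse coordinate map to image (bilinear) and mask (nearest)."""
    img = sktransform.warp(
        image.astype(np.float64) / 255.0, inverse_map, order=1, mode="reflect"
    )
    msk = sktransform.warp(mask.astype(np.float64), inverse_map, order=0, mode="reflect")
    return (np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8), msk.astype(np.uint8))


def _shift_scale_rotate(image, mask, rng, shift_limit=0.0625, scale_limit=0.1, rotate_limit=15.0):
    h, w = mask.shape
    angle = np.deg2rad(rng.uniform(-rotate_limit, rotate_limit))
    scale = rng.uniform(1.0 - scale_limit, 1.0 + scale_limit)
    tr = (rng.uniform(-shift_limit, shift_limit) * h, rng.uniform(-shift_limit, shift_limit) * w)
    center = np.array([w / 2.0, h / 2.0])
    t = (
        sktransform.AffineTransform(translation=-center)
        + sktransform.AffineTransform(rotation=angle, scale=scale)
        + sktransform.AffineTransform(translation=center + tr[::-1])
    )
    return _warp_pair(image, mask, t.inverse)


def _displacement_warp(image, mask, dr, dc):
    h, w = mask.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rows + dr, cols + dc])
    img = np.stack(
        [ndi.map_coordinates(image[..., k].astype(np.float64), coords, order=1, mode="reflect") for k in range(3)],
        axis=-1,
    )
    msk = ndi.map_coordinates(mask, coords, order=0, mode="reflect")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), msk.astype(np.uint8)


def _elastic_transform(image, mask, rng):
    h, w = mask.shape
    alpha, sigma = 0.08 * h, 0.05 * h
    dr = ndi.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dc = ndi.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    return _displacement_warp(image, mask, dr, dc)


def _grid_distortion(image, mask, rng, steps: int = 5, limit: float = 0.3):
    h, w = mask.shape
    coarse_r = rng.uniform(-limit, limit, (steps, steps)) * (h / steps)
    coarse_c = rng.uniform(-limit, limit, (steps, steps)) * (w / steps)
    dr = sktransform.resize(coarse_r, (h, w), order=1, mode="edge")
    dc = sktransform.resize(coarse_c, (h, w), order=1, mode="edge")
    return _displacement_warp(image, mask, dr, dc)


def _optical_distortion(image, mask, rng, limit: float = 0.1):
    h, w = mask.shape
    k = rng.uniform(-limit, limit)
    rows, cols = np.meshgrid(
        (np.arange(h) - h / 2.0) / (h / 2.0),
        (np.arange(w) - w / 2.0) / (w / 2.0),
        indexing="ij",
    )
    r2 = rows**2 + cols**2
    dr = rows * k * r2 * (h / 2.0)
    dc = cols * k * r2 * (w / 2.0)
    return _displacement_warp(image, mask, dr, dc)


def _random_gamma(image, mask, rng):
    gamma = rng.uniform(0.8, 1.25)
    img = 255.0 * (image.astype(np.float64) / 255.0) ** gamma
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def _random_brightness(image, mask, rng):
    factor = 1.0 + rng.uniform(-0.2, 0.2)
    return np.clip(np.rint(image.astype(np.float64) * factor), 0, 255).astype(np.uint8), mask


def _rgb_shift(image, mask, rng):
    shift = rng.uniform(-20, 20, size=3)
    return np.clip(np.rint(image.astype(np.float64) + shift), 0, 255).astype(np.uint8), mask


def _hue_saturation_value(image, mask, rng):
    hsv = skcolor.rgb2hsv(image)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-0.03, 0.03)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + rng.uniform(-0.2, 0.2)), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1.0 + rng.uniform(-0.2, 0.2)), 0, 1)
    return np.clip(np.rint(skcolor.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8), mask


def _color_jitter(image, mask, rng):
    img = image.astype(np.float64)
    img *= 1.0 + rng.uniform(-0.2, 0.2)  # brightness
    mean = img.mean()
    img = mean + (img - mean) * (1.0 + rng.uniform(-0.2, 0.2))  # contrast
    gray = img.mean(axis=-1, keepdims=True)
    img = gray + (img - gray) * (1.0 + rng.uniform(-0.2, 0.2))  # saturation
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def _convolve_rgb(image, kernel):
    img = np.stack(
        [ndi.convolve(image[..., k].astype(np.float64), kernel, mode="reflect") for k in range(3)],
        axis=-1,
    )
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _defocus_blur(image, mask, rng):
    radius = int(rng.integers(2, 5))
    rr, cc = skdraw.disk((radius, radius), radius + 0.5)
    kernel = np.zeros((2 * radius + 1, 2 * radius + 1))
    kernel[rr, cc] = 1.0
    kernel /= kernel.sum()
    return _convolve_rgb(image, kernel), mask


def _motion_blur(image, mask, rng):
    length = int(rng.integers(5, 10))
    angle = rng.uniform(0, np.pi)
    kernel = np.zeros((length, length))
    c = (length - 1) / 2.0
    r0 = int(round(c - c * np.sin(angle)))
    c0 = int(round(c - c * np.cos(angle)))
    r1 = int(round(c + c * np.sin(angle)))
    c1 = int(round(c + c * np.cos(angle)))
    rr, cc = skdraw.line(r0, c0, r1, c1)
    kernel[rr, cc] = 1.0
    kernel /= kernel.sum()
    return _convolve_rgb(image, kernel), mask


def _gaussian_blur(image, mask, rng):
    sigma = rng.uniform(0.5, 1.5)
    img = ndi.gaussian_filter(image.astype(np.float64), sigma=(sigma, sigma, 0))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


AUGMENTATIONS: dict[str, Callable] = {
    "shift_scale_rotate": _shift_scale_rotate,
    "elastic_transform": _elastic_transform,
    "grid_distortion": _grid_distortion,
    "optical_distortion": _optical_distortion,
    "random_gamma": _random_gamma,
    "random_brightness": _random_brightness,
    "rgb_shift": _rgb_shift,
    "hue_saturation_value": _hue_saturation_value,
    "color_jitter": _color_jitter,
    "defocus_blur": _defocus_blur,
    "motion_blur": _motion_blur,
    "gaussian_blur": _gaussian_blur,
}

GEOMETRIC = {"shift_scale_rotate", "elastic_transform", "grid_distortion", "optical_distortion"}


def augment(patch: AnnotatedPatch, menu: Sequence[str], seed: int | np.random.Generator) -> AnnotatedPatch:
    """Apply the named transforms in menu order; each fires with p=0.5."""
    unknown = [m for m in menu if m not in AUGMENTATIONS]
    if unknown:
        raise KeyError(f"unknown augmentation(s) {unknown}; registered: {sorted(AUGMENTATIONS)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    image, mask = patch.image, patch.mask
    for name in menu:
        if rng.random() < 0.5:
            image, mask = AUGMENTATIONS[name](image, mask, rng)
    return AnnotatedPatch(image=image, mask=mask, origin=patch.origin, tubule_count=patch.tubule_count)


# ==================================================================== config
@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    lr: float = 1e-4
    batch_size: int = 16
    lr_step_epoch: int = 30
    lr_factor: float = 0.1
    patience: int = 15
    loss_tolerance: float = 1e-4
    pad_mode: str = "none"  # reflection | mirror | none
    mirror_margin: int = 100
    loss_region: str = "full"  # full padded canvas, or "core" only
    augmentations: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.lr_factor <= 1:
            raise ValueError("lr_factor must be in (0, 1]")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.pad_mode not in ("reflection", "mirror", "none"):
            raise ValueError(f"unknown pad_mode: {self.pad_mode!r}")
        if self.loss_region not in ("full", "core"):
            raise ValueError(f"unknown loss_region: {self.loss_region!r}")
        unknown = [m for m in self.augmentations if m not in AUGMENTATIONS]
        if unknown:
            raise KeyError(f"unknown augmentation(s): {unknown}")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: Optional[float]
    val_dsc: Optional[float]
    lr: float


@dataclass
class TrainLog:
    epochs: list[EpochRecord] = field(default_factory=list)
    stop_reason: str = "completed"
    best_epoch: int = 0

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss", "val_dsc", "lr"])
            for r in self.epochs:
                writer.writerow([r.epoch, r.train_loss, r.val_loss, r.val_dsc, r.lr])


# ====================================================================== fit
def _prepare_sample(
    patch: AnnotatedPatch, config: TrainConfig, input_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Pad per config, resize to the network input, return (x, y, loss weight)."""
    if config.pad_mode == "reflection":
        padded = reflection_pad(patch)
    elif config.pad_mode == "mirror":
        padded = mirror_pad(patch, margin=config.mirror_margin)
    else:
        padded = None
    if padded is None:
        img, msk = patch.image, patch.mask
        core = None
    else:
        img, msk = padded.image, padded.mask
        core = padded.core_box
    side = img.shape[0]
    x = resize(img, input_size).astype(np.float32) / 255.0
    y = resize(msk.astype(np.uint8), input_size).astype(np.float32)
    weight = None
    if config.loss_region == "core" and core is not None:
        scale = input_size / side
        r0, c0, r1, c1 = (int(round(v * scale)) for v in core)
        weight = np.zeros((input_size, input_size), dtype=np.float32)
        weight[r0:r1, c0:c1] = 1.0
    return x.transpose(2, 0, 1), y, weight


def _epoch_lr(config: TrainConfig, epoch: int) -> float:
    """Single-step decay: epochs past ``lr_step_epoch`` use lr * lr_factor."""
    return config.lr * (config.lr_factor if epoch > config.lr_step_epoch else 1.0)


def _validate(
    model: SegmentationModel, val_xy: list[tuple[np.ndarray, np.ndarray, np.ndarray | None]], batch: int
) -> tuple[float, float]:
    model.eval()
    losses = []
    tp = fp = fn = tn = 0
    for i in range(0, len(val_xy), batch):
        chunk = val_xy[i : i + batch]
        x = np.stack([c[0] for c in chunk])
        y = np.stack([c[1] for c in chunk])[:, None]
        logits = model.forward_logits(nn.Tensor(x))
        losses.append(float(F.bce_with_logits(logits, y).data) * len(chunk))
        pred = binarize(1.0 / (1.0 + np.exp(-logits.data[:, 0])))
        rep = score(pred, y[:, 0] >= 0.5)
        tp, fp, fn, tn = tp + rep.tp, fp + rep.fp, fn + rep.fn, tn + rep.tn
    denom = 2 * tp + fp + fn
    dsc = 1.0 if denom == 0 else 2.0 * tp / denom
    return sum(losses) / len(val_xy), dsc


def fit(
    model: SegmentationModel,
    train_set: list[AnnotatedPatch],
    val_set: list[AnnotatedPatch],
    config: TrainConfig,
    val_loss_fn: Callable[[int], float] | None = None,
) -> tuple[SegmentationModel, TrainLog]:
    """Train with Adam on mean per-pixel binary cross entropy.

    Early stopping: training halts once the validation loss has failed to
    improve by more than ``loss_tolerance`` for ``patience`` consecutive
    epochs; the returned model carries the best-validation-loss weights.
    ``val_loss_fn`` is a diagnostic hook mapping epoch -> validation loss,
    replacing the computed one (used to exercise the stopping contract).
    """
    config.validate()
    if not train_set:
        raise ValueError("train_set must not be empty")
    rng = np.random.default_rng(config.seed)
    input_size = model.spec.input_size
    optimizer = nn.Adam(model.parameters(), lr=config.lr)

    static_train = None
    if not config.augmentations:
        static_train = [_prepare_sample(p, config, input_size) for p in train_set]
    val_xy = [_prepare_sample(p, config, input_size) for p in val_set]

    log = TrainLog()
    best_loss = np.inf
    best_state: list[np.ndarray] | None = None
    best_epoch = 0
    streak = 0
    has_val = bool(val_set) or val_loss_fn is not None

    for epoch in range(1, config.epochs + 1):
        optimizer.lr = _epoch_lr(config, epoch)
        model.train()
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            if static_train is not None:
                chunk = [static_train[j] for j in idx]
            else:
                chunk = [
                    _prepare_sample(augment(train_set[j], config.augmentations, rng), config, input_size)
                    for j in idx
                ]
            x = np.stack([c[0] for c in chunk])
            y = np.stack([c[1] for c in chunk])[:, None]
            w = None
            if chunk[0][2] is not None:
                w = np.stack([c[2] for c in chunk])[:, None]
            logits = model.forward_logits(nn.Tensor(x))
            loss = F.bce_with_logits(logits, y, weight=w)
            model.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data) * len(idx))
        train_loss = sum(epoch_losses) / len(train_set)

        val_loss = val_dsc = None
        if val_loss_fn is not None:
            val_loss = float(val_loss_fn(epoch))
        elif val_set:
            val_loss, val_dsc = _validate(model, val_xy, config.batch_size)

        log.epochs.append(EpochRecord(epoch, train_loss, val_loss, val_dsc, optimizer.lr))

        if has_val and val_loss is not None:
            if val_loss < best_loss - config.loss_tolerance:
                best_loss = val_loss
                best_epoch = epoch
                best_state = [a.copy() for a in model.state_arrays()]
                streak = 0
            else:
                streak += 1
                if streak >= config.patience:
                    log.stop_reason = "early_stop"
                    break
        else:
            best_epoch = epoch

    log.best_epoch = best_epoch if best_epoch else len(log.epochs)
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, log
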