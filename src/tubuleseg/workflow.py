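"""Run configuration and the end-to-end tile/predict/stitch workflow."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluation import binarize
from .model import SegModelSpec, SegmentationModel, load_model, predict_patch
from .phantom import AnnotatedPatch
from .tiling import extract_tiles, plan_tiles, stitch
from . import io as tio
from .training import TrainConfig

__all__ = ["RunConfig", "run_inference", "predict_image"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one train/infer/evaluate run."""

    data_dir: str = "data"
    output_dir: str = "out"
    checkpoint: str = "model"
    model: SegModelSpec = field(default_factory=SegModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    core: int = 900
    overlap_fraction: float = 0.25
    blend: str = "core_crop"
    pad_mode: str = "none"
    threshold: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("encoder_channels", "decoder_channels"):
            if d["model"][k] is not None:
                d["model"][k] = list(d["model"][k])
        d["train"]["augmentations"] = list(d["train"]["augmentations"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls._from_dict(data)

    @classmethod
    def _from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "model" in kwargs and isinstance(kwargs["model"], dict):
            m = kwargs["model"]
            bad = set(m) - {f.name for f in dataclasses.fields(SegModelSpec)}
            if bad:
                raise ValueError(f"unknown model keys: {sorted(bad)}")
            for k in ("encoder_channels", "decoder_channels"):
                if m.get(k) is not None:
                    m[k] = tuple(m[k])
            kwargs["model"] = SegModelSpec(**m)
        if "train" in kwargs and isinstance(kwargs["train"], dict):
            t = kwargs["train"]
            bad = set(t) - {f.name for f in dataclasses.fields(TrainConfig)}
            if bad:
                raise ValueError(f"unknown train keys: {sorted(bad)}")
            if "augmentations" in t:
                t["augmentations"] = tuple(t["augmentations"])
            kwargs["train"] = TrainConfig(**t)
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def predict_image(
    model: SegmentationModel,
    image: np.ndarray,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile a large image, predict per tile, stitch, threshold.

    Per-tile pipeline: extract the overlap tile, pad/resize per config, run
    the network, resize the probability map back to tile size, then stitch.
    Returns (probability map, binary mask) at the input resolution.
    """
    height, width = image.shape[:2]
    plan = plan_tiles(height, width, core=config.core, overlap_fraction=config.overlap_fraction)
    parent = AnnotatedPatch(image=image, mask=np.zeros((height, width), dtype=np.uint8))
    tiles = extract_tiles(parent, plan)
    maps = [predict_patch(model, t, pad_mode=config.pad_mode) for t in tiles]
    prob = stitch(maps, plan, blend=config.blend)
    return prob, binarize(prob, config.threshold)


def run_inference(
    image_path: str | Path,
    checkpoint: str | Path,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Load image + checkpoint, run :func:`predict_image`, persist outputs.

    Writes ``<stem>_prob.png`` (16-bit), ``<stem>_mask.png`` and a provenance
    sidecar JSON into ``config.output_dir``.
    """
    image_path = Path(image_path)
    image = tio.read_image(image_path)
    model = load_model(checkpoint)
    if model.spec.input_size % 32 != 0:
        raise ValueError("checkpoint/model spec mismatch: input size not divisible by 32")
    prob, mask = predict_image(model, image, config)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = image_path.stem
    tio.write_probability_map(prob, out_dir / f"{stem}_prob.png")
    tio.write_mask(mask, out_dir / f"{stem}_mask.png")
    tio.write_sidecar(
        out_dir / f"{stem}_sidecar.json",
        config_hash=config.config_hash(),
        inputs=[image_path],
        extra={"threshold": config.threshold, "blend": config.blend},
    )
    return prob, mask
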