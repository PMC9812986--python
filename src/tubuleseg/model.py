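"""Symmetric and asymmetric U-Net segmentation models.

The decoder is shared across all backbones: five upsampling stages, each a
2x2 transposed convolution followed by concatenation with the stride-matched
encoder feature and two 3x3 convolution + ReLU pairs; a 1x1 convolution with
sigmoid produces the single-channel probability map.  The encoder is either
the classic U-Net contracting path (``basic``/``tiny``) or one of the
classification backbones ResNet34 / DenseNet161 / EfficientNet-B3 with skip
connections taken at the stride-matched stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import nn
from .nn import functional as F
from .nn.backbones import ENCODER_REGISTRY
from .padding import mirror_pad, reflection_pad, resize
from .phantom import AnnotatedPatch

__all__ = ["SegModelSpec", "SegmentationModel", "build_model", "predict_patch", "save_model", "load_model"]

DEFAULT_DECODER = (256, 128, 64, 32, 16)
TINY_DECODER = (32, 32, 16, 16, 8)


@dataclass(frozen=True)
class SegModelSpec:
    """Architecture description of one segmentation network."""

    backbone: str = "basic"
    input_size: int = 512
    encoder_channels: Optional[tuple[int, ...]] = None  # basic/tiny only
    decoder_channels: Optional[tuple[int, ...]] = None
    pretrained: bool = False

    def validate(self) -> None:
        if self.backbone not in ENCODER_REGISTRY:
            raise KeyError(
                f"unknown backbone {self.backbone!r}; registered: {sorted(ENCODER_REGISTRY)}"
            )
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32 (five stride-2 stages)")
        if self.pretrained:
            raise ValueError(
                "no pretrained weight source is bundled; build with pretrained=False "
                "and train, or load a saved checkpoint"
            )

    def resolved_decoder(self) -> tuple[int, ...]:
        if self.decoder_channels is not None:
            dc = tuple(self.decoder_channels)
        else:
            dc = TINY_DECODER if self.backbone == "tiny" else DEFAULT_DECODER
        if len(dc) != 5:
            raise ValueError("decoder_channels needs exactly 5 widths")
        return dc

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("encoder_channels", "decoder_channels"):
            if d[k] is not None:
                d[k] = list(d[k])
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "SegModelSpec":
        d = yaml.safe_load(text)
        for k in ("encoder_channels", "decoder_channels"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


class DecoderStage(nn.Module):
    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.up = nn.ConvTranspose2x2(in_ch, out_ch, rng=rng)
        self.conv1 = nn.Conv2d(out_ch + skip_ch, out_ch, 3, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng)

    def forward_with_skip(self, x: nn.Tensor, skip: Optional[nn.Tensor]) -> nn.Tensor:
        x = self.up(x)
        if skip is not None:
            x = F.concat([x, skip], axis=1)
        x = F.relu(self.conv1(x))
        return F.relu(self.conv2(x))


class SegmentationModel(nn.Module):
    """Encoder-decoder network mapping NCHW RGB to a same-size probability map."""

    def __init__(self, spec: SegModelSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.encoder = ENCODER_REGISTRY[spec.backbone](rng, spec.encoder_channels)
        enc_ch = self.encoder.feature_channels  # strides 2..32
        dec_ch = spec.resolved_decoder()
        skips = [enc_ch[3], enc_ch[2], enc_ch[1], enc_ch[0], 0]
        ins = [enc_ch[4]] + list(dec_ch[:-1])
        self.decoder = [
            DecoderStage(i, s, o, rng) for i, s, o in zip(ins, skips, dec_ch)
        ]
        self.head = nn.Conv2d(dec_ch[-1], 1, 1, rng=rng)

    # ------------------------------------------------------------------ core
    def encoder_features(self, x: nn.Tensor) -> list[nn.Tensor]:
        self._check_input(x.shape)
        return self.encoder(x)

    def forward_logits(self, x: nn.Tensor) -> nn.Tensor:
        feats = self.encoder_features(x)
        out = feats[4]
        skips = [feats[3], feats[2], feats[1], feats[0], None]
        for stage, skip in zip(self.decoder, skips):
            out = stage.forward_with_skip(out, skip)
        return self.head(out)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return F.sigmoid(self.forward_logits(x))

    def _check_input(self, shape: tuple[int, ...]) -> None:
        if len(shape) != 4 or shape[1] != 3:
            raise ValueError(f"expected NCHW RGB input, got shape {shape}")
        if shape[2] % 32 or shape[3] % 32:
            raise ValueError(f"spatial size {shape[2:]} must be divisible by 32")

    # ------------------------------------------------------------- inference
    def predict(self, images: np.ndarray) -> np.ndarray:
        """Probability maps for a batch of HxWx3 uint8 (or [0,1] float) images."""
        x = _to_nchw(images)
        was_training = self.training
        self.eval()
        try:
            probs = self.forward(nn.Tensor(x)).data[:, 0]
        finally:
            if was_training:
                self.train()
        return probs


def _to_nchw(images: np.ndarray) -> np.ndarray:
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected (N,)H,W,3 images, got {arr.shape}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2).astype(np.float32))


def build_model(spec: SegModelSpec, seed: int = 0) -> SegmentationModel:
    """Instantiate a randomly initialised model from its spec."""
    return SegmentationModel(spec, seed=seed)


def predict_patch(
    model: SegmentationModel,
    patch: np.ndarray | AnnotatedPatch,
    pad_mode: str = "none",
    margin: int = 100,
) -> np.ndarray:
    """Probability map for one patch at its original resolution.

    Pipeline: apply ``pad_mode`` -> resize to the model input size -> forward
    pass -> resize the map back to the padded size -> crop the core region.
    """
    image = patch.image if isinstance(patch, AnnotatedPatch) else np.asarray(patch)
    ap = AnnotatedPatch(image=image, mask=np.zeros(image.shape[:2], dtype=np.uint8))
    if pad_mode == "reflection":
        padded = reflection_pad(ap)
    elif pad_mode == "mirror":
        padded = mirror_pad(ap, margin=margin)
    elif pad_mode == "none":
        padded = None
    else:
        raise ValueError(f"unknown pad_mode: {pad_mode!r}")

    canvas = image if padded is None else padded.image
    side = canvas.shape[0]
    target = model.spec.input_size
    net_in = canvas if (side == target and canvas.shape[1] == target) else resize(canvas, target)
    prob = model.predict(net_in)[0]
    if prob.shape != canvas.shape[:2]:
        prob = resize(prob.astype(np.float32), side)
    if padded is None:
        return prob.astype(np.float32)
    r0, c0, r1, c1 = padded.core_box
    return prob[r0:r1, c0:c1].astype(np.float32)


# ------------------------------------------------------------------ storage
def save_model(model: SegmentationModel, path: str | Path) -> None:
    """Checkpoint = npz of parameter/buffer arrays + YAML spec sidecar."""
    base = Path(path).with_suffix("")
    arrays = model.state_arrays()
    np.savez(base.with_suffix(".npz"), **{f"arr_{i}": a for i, a in enumerate(arrays)})
    base.with_suffix(".yaml").write_text(model.spec.to_yaml())


def load_model(path: str | Path, spec: SegModelSpec | None = None) -> SegmentationModel:
    base = Path(path).with_suffix("")
    if spec is None:
        spec = SegModelSpec.from_yaml(base.with_suffix(".yaml").read_text())
    with np.load(base.with_suffix(".npz")) as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    model = SegmentationModel(spec, seed=0)
    model.load_state_arrays(arrays)
    return model
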