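"""Layer/module abstraction over the functional ops.

Modules own their parameters (Tensors with ``requires_grad=True``) and any
running buffers (plain arrays).  Weight initialisation draws from the
``numpy.random.Generator`` passed to each constructor, so a model built twice
from the same seed has identical weights.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "MaxPool2d",
    "ReLU",
    "SiLU",
    "Identity",
]


class Module:
    """Base class: child modules and parameters are discovered by attribute scan."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    # -------------------------------------------------------------- traversal
    def children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self.children():
            params.extend(child.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        bufs = [v for k, v in self.__dict__.items() if isinstance(v, np.ndarray)]
        for child in self.children():
            bufs.extend(child.buffers())
        return bufs

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self) -> "Module":
        self.training = True
        for child in self.children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for child in self.children():
            child.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # ------------------------------------------------------------ state dicts
    def state_arrays(self) -> list[np.ndarray]:
        """Parameters then buffers, in deterministic traversal order."""
        return [p.data for p in self.parameters()] + self.buffers()

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = self.parameters()
        n = len(targets)
        if len(arrays) != n + len(self.buffers()):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects "
                f"{n + len(self.buffers())}"
            )
        for p, a in zip(targets, arrays[:n]):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32).copy()
        for buf, a in zip(self.buffers(), arrays[n:]):
            buf[...] = a


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(
        self,
        channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_init(rng, (channels, kernel, kernel), kernel * kernel), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv2d(x, self.weight, stride=self.stride, padding=self.padding)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (the U-Net upsampling operator)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int = 2, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.maxpool2d(x, self.kernel, self.stride, self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.silu(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
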