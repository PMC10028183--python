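"""Neural-network modules on top of the autodiff engine.

Mirrors the familiar layer vocabulary (conv / depthwise conv / batch norm /
linear / SE block / dropout) with explicit seeded initialisation: every
layer takes the weights it needs from a ``numpy.random.Generator`` passed
at construction, so a model built twice from the same generator state is
bit-identical.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(prefix=name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialisation -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Module):
                yield from v.named_buffers(prefix=name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{name}.{i}.")
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                yield name, v

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {value.shape}"
                    )
                params[name].data = value.astype(np.float32).copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected state entry {name!r}")


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """2-D convolution (cross-correlation), optionally with bias.

    Kernels may be asymmetric (e.g. 1x3 / 3x1); padding defaults to "same"
    for stride 1.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: int | tuple[int, int], rng: np.random.Generator,
                 stride: int = 1, padding: int | tuple[int, int] | None = None,
                 bias: bool = False):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if padding is None:
            padding = (kh // 2, kw // 2)
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kh * kw
        self.weight = Tensor(
            kaiming_normal(rng, (out_channels, in_channels, kh, kw), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
            if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        out = T.conv2d(x, self.weight, stride=self.stride, padding=self.padding)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class DepthwiseConv2d(Module):
    """Per-channel convolution (groups = channels)."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = kernel_size // 2
        self.stride = stride
        self.padding = padding
        fan_in = kernel_size * kernel_size
        self.weight = Tensor(
            kaiming_normal(rng, (channels, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )

    def __call__(self, x: Tensor) -> Tensor:
        return T.depthwise_conv2d(x, self.weight, stride=self.stride,
                                  padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, training=self.training,
                            momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(
            kaiming_normal(rng, (in_features, out_features), in_features),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)
            if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU, the default stage wrapper."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: int | tuple[int, int], rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng, stride=stride)
        self.bn = BatchNorm2d(out_channels)

    def __call__(self, x: Tensor) -> Tensor:
        return T.relu(self.bn(self.conv(x)))


class DwConvBNReLU(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.conv = DepthwiseConv2d(channels, kernel_size, rng, stride=stride)
        self.bn = BatchNorm2d(channels)

    def __call__(self, x: Tensor) -> Tensor:
        return T.relu(self.bn(self.conv(x)))


class SEBlock(Module):
    """Squeeze-and-excitation: global pooling, gated bottleneck, rescale.

    The bottleneck width is ``channels // reduction`` clamped to at least
    ``min_width``.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 min_width: int = 4):
        super().__init__()
        hidden = max(channels // reduction, min_width)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.channels = channels

    def channel_weights(self, x: Tensor) -> Tensor:
        """Sigmoid gate per channel, shape (N, C)."""
        squeeze = T.mean(x, axis=(2, 3))
        return T.sigmoid(self.fc2(T.relu(self.fc1(squeeze))))

    def __call__(self, x: Tensor) -> Tensor:
        w = self.channel_weights(x)
        n, c = w.shape
        return x * w.reshape(n, c, 1, 1)


class ChannelAttention(Module):
    """SE-style channel gate used inside the cross-attention block.

    Single-path: the channel descriptor is the spatial average alone
    (optionally average+max for the dual-path ablation).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 dual_path: bool = False, min_width: int = 4):
        super().__init__()
        hidden = max(channels // reduction, min_width)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.dual_path = dual_path

    def __call__(self, x: Tensor) -> Tensor:
        """Returns channel weights in (0,1), shape (N, C, 1, 1)."""
        logits = self.fc2(T.relu(self.fc1(T.mean(x, axis=(2, 3)))))
        if self.dual_path:
            mx = Tensor(x.data.max(axis=(2, 3)))  # descriptor, not differentiated
            logits = logits + self.fc2(T.relu(self.fc1(mx)))
        w = T.sigmoid(logits)
        n, c = w.shape
        return w.reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Spatial gate: channel-mean map -> kxk conv -> sigmoid.

    Single-path (mean descriptor only); the dual-path ablation appends the
    channel-max map as a second descriptor channel.
    """

    def __init__(self, kernel_size: int, rng: np.random.Generator,
                 dual_path: bool = False):
        super().__init__()
        in_ch = 2 if dual_path else 1
        self.conv = Conv2d(in_ch, 1, kernel_size, rng, bias=True)
        self.dual_path = dual_path

    def __call__(self, x: Tensor) -> Tensor:
        """Returns spatial weights in (0,1), shape (N, 1, H, W)."""
        desc = T.mean(x, axis=1, keepdims=True)
        if self.dual_path:
            mx = Tensor(x.data.max(axis=1, keepdims=True))
            desc = T.concat([desc, mx], axis=1)
        return T.sigmoid(self.conv(desc))


class Dropout(Module):
    """Inverted dropout; the mask is drawn from a generator owned here."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)
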