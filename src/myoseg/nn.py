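"""Layers and the SGD-with-momentum optimizer for the segmentation network.

Layers are thin parameter holders whose ``__call__`` builds the autodiff
graph.  Convolutions use He-normal initialization (appropriate for ReLU
networks); transposed convolutions are initialized to bilinear
interpolation so an untrained decoder already performs sensible
upsampling.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Conv2d", "ConvTranspose2d", "SGD", "bilinear_kernel"]


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def bilinear_kernel(channels_in: int, channels_out: int, k: int) -> np.ndarray:
    """(Cin, Cout, k, k) transposed-conv weight performing bilinear upsampling."""
    factor = (k + 1) // 2
    center = factor - 1 if k % 2 == 1 else factor - 0.5
    og = np.ogrid[:k, :k]
    filt = (1 - abs(og[0] - center) / factor) * (1 - abs(og[1] - center) / factor)
    w = np.zeros((channels_in, channels_out, k, k), dtype=np.float32)
    for c in range(min(channels_in, channels_out)):
        w[c, c] = filt
    return w


class Conv2d:
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        name: str = "",
    ):
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            requires_grad=True,
            name=f"{name}.weight",
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True, name=f"{name}.bias")
        self.stride = stride
        self.padding = padding
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class ConvTranspose2d:
    """Learnable stride-2 upsampling (kernel 4, padding 1 -> exact x2)."""

    def __init__(self, in_channels: int, out_channels: int, name: str = "", kernel_size: int = 4, stride: int = 2, padding: int = 1):
        self.weight = Tensor(bilinear_kernel(in_channels, out_channels, kernel_size), requires_grad=True, name=f"{name}.weight")
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True, name=f"{name}.bias")
        self.stride = stride
        self.padding = padding
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class SGD:
    """Stochastic gradient descent with classical momentum.

    v <- momentum * v + grad;  p <- p - lr * v
    """

    def __init__(
        self,
        parameters: Iterable[Tensor],
        lr: float,
        momentum: float = 0.9,
        clip_grad_norm: Optional[float] = None,
    ):
        self.parameters = list(parameters)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.clip_grad_norm = clip_grad_norm
        self._velocity = [np.zeros_like(p.data) for p in self.parameters]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad = None

    def _clip(self) -> None:
        total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for p in self.parameters if p.grad is not None))
        if total > self.clip_grad_norm and total > 0:
            scale = np.float32(self.clip_grad_norm / total)
            for p in self.parameters:
                if p.grad is not None:
                    p.grad *= scale

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else float(lr)
        if self.clip_grad_norm is not None:
            self._clip()
        for p, v in zip(self.parameters, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= lr * v
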