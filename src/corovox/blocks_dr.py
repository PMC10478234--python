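"""Convolutional blocks for the encoder/decoder stages.

Three interchangeable blocks at equal channel widths:

* ``PlainBlock`` — two conv+ReLU units, Y = H2(H1(X)).
* ``ResidualBlock`` — classic residual, Y = P(X) + H2(H1(X)).
* ``DenseResidualBlock`` — two nested residual connections that keep every
  intermediate feature map::

      A1 = H1(X);  A2 = H2(A1);  R = P(X) + A2;  A3 = H3(R)
      Y  = P(X) + A1 + A2 + A3

``H`` is a 3x3x3 convolution followed by ReLU (optionally with batch
normalisation in between for training presets); ``P`` is a pointwise
projection when the input channel count differs from the block width and the
identity otherwise.  The dense variant preserves shallow features (thin
distal vessels, low-contrast boundaries) that repeated convolution would
otherwise wash out, at the cost of one extra convolution unit.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor
from .nn import Conv3d, ConvUnit, Module

__all__ = ["PlainBlock", "ResidualBlock", "DenseResidualBlock",
           "residual_forward", "dr_forward"]


class _Block(Module):
    def __init__(self, in_channels: int, channels: int, norm: bool,
                 rng: np.random.Generator | None, dtype):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.channels = channels
        self.h1 = ConvUnit(in_channels, channels, norm=norm, rng=rng, dtype=dtype)
        self.h2 = ConvUnit(channels, channels, norm=norm, rng=rng, dtype=dtype)

    def _check(self, x: Tensor) -> None:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"block expects {self.in_channels} input channels, got {x.shape[1]}"
            )


class PlainBlock(_Block):
    """Two stacked conv+ReLU units, no shortcut."""

    def __init__(self, in_channels: int, channels: int, norm: bool = False,
                 rng=None, dtype=np.float32):
        super().__init__(in_channels, channels, norm, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        self._check(x)
        return self.h2(self.h1(x))


class _Projected(_Block):
    def __init__(self, in_channels: int, channels: int, norm: bool,
                 rng, dtype):
        super().__init__(in_channels, channels, norm, rng, dtype)
        self.proj = (
            Conv3d(in_channels, channels, k=1, rng=rng or np.random.default_rng(0),
                   dtype=dtype)
            if in_channels != channels
            else None
        )

    def _project(self, x: Tensor) -> Tensor:
        return x if self.proj is None else self.proj(x)


class ResidualBlock(_Projected):
    """Y = P(X) + H2(H1(X))."""

    def __init__(self, in_channels: int, channels: int, norm: bool = False,
                 rng=None, dtype=np.float32):
        super().__init__(in_channels, channels, norm, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        self._check(x)
        return self._project(x) + self.h2(self.h1(x))


class DenseResidualBlock(_Projected):
    """Two nested residual connections summing every intermediate feature map."""

    def __init__(self, in_channels: int, channels: int, norm: bool = False,
                 rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        super().__init__(in_channels, channels, norm, rng, dtype)
        self.h3 = ConvUnit(channels, channels, norm=norm, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        self._check(x)
        p = self._project(x)
        a1 = self.h1(x)
        a2 = self.h2(a1)
        r = p + a2
        a3 = self.h3(r)
        return p + a1 + a2 + a3


def _apply(block: Module, x):
    if isinstance(x, Tensor):
        return block(x)
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"expected a (C, D, H, W) feature map, got shape {x.shape}")
    return block(Tensor(x[None])).data[0]


def residual_forward(x, block: ResidualBlock):
    """Run a residual block on a (C, D, H, W) feature map."""
    return _apply(block, x)


def dr_forward(x, block: DenseResidualBlock):
    """Run a dense-residual block on a (C, D, H, W) feature map."""
    return _apply(block, x)
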