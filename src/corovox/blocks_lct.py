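"""Local contextual attention block used on the skip connections.

Plain self-attention embeds queries, keys and values with pointwise (1x1x1)
convolutions, so the attention weight of each voxel is computed from an
isolated query-key pair.  The local contextual variant instead embeds keys and
values with grouped k x k x k convolutions, so each key/value already
aggregates its spatial neighbourhood before the query-key fusion.  The
pipeline is::

    Q = Wq * X                 (pointwise)
    K = Wk * X                 (grouped k^3, 'same' padding)
    V = Wv * X                 (grouped k^3, 'same' padding)
    A = ReLU(fuse * [K; Q])    (pointwise 2C -> C)
    Y = softmax_channels(A (*) V)

where ``(*)`` is the element-wise product.  The softmax runs over the channel
axis so the output keeps the input shape and every voxel's channel vector is a
probability vector; it can be switched off for ablation.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat, relu, softmax
from .nn import Conv3d, Module

__all__ = ["LCTBlock", "make_sa_block", "lct_forward", "sa_forward",
           "ChannelMismatchError"]


class ChannelMismatchError(ValueError):
    """Input channel count does not match the block's configuration."""


class LCTBlock(Module):
    """Contextual attention over a (C, D, H, W) feature map.

    ``k=1, groups=1`` degenerates to plain self-attention; that configuration
    is what :func:`make_sa_block` returns for the ablation baseline.
    """

    def __init__(
        self,
        channels: int,
        k: int = 3,
        groups: int = 4,
        channel_softmax: bool = True,
        pad_mode: str = "zeros",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if k % 2 == 0 or k < 1:
            raise ValueError(f"k must be odd and positive, got {k}")
        if channels % groups:
            raise ValueError(f"groups={groups} must divide channels={channels}")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.k = k
        self.groups = groups
        self.channel_softmax = channel_softmax
        self.w_q = Conv3d(channels, channels, k=1, rng=rng, dtype=dtype)
        self.w_k = Conv3d(channels, channels, k=k, groups=groups,
                          pad_mode=pad_mode, rng=rng, dtype=dtype)
        self.w_v = Conv3d(channels, channels, k=k, groups=groups,
                          pad_mode=pad_mode, rng=rng, dtype=dtype)
        self.fuse = Conv3d(2 * channels, channels, k=1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ChannelMismatchError(
                f"block built for {self.channels} channels, input has {x.shape[1]}"
            )
        q = self.w_q(x)
        k = self.w_k(x)
        v = self.w_v(x)
        attn = relu(self.fuse(concat([k, q], axis=1)))
        gated = attn * v
        return softmax(gated, axis=1) if self.channel_softmax else gated


def make_sa_block(
    channels: int,
    channel_softmax: bool = True,
    pad_mode: str = "zeros",
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> LCTBlock:
    """Plain self-attention baseline: all three embeddings pointwise."""
    return LCTBlock(channels, k=1, groups=1, channel_softmax=channel_softmax,
                    pad_mode=pad_mode, rng=rng, dtype=dtype)


def _apply(block: LCTBlock, x) -> np.ndarray | Tensor:
    if isinstance(x, Tensor):
        return block(x)
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"expected a (C, D, H, W) feature map, got shape {x.shape}")
    return block(Tensor(x[None])).data[0]


def lct_forward(x, block: LCTBlock):
    """Run the contextual attention block on a (C, D, H, W) feature map."""
    return _apply(block, x)


def sa_forward(x, block: LCTBlock):
    """Run the self-attention baseline; requires a k=1, groups=1 block."""
    if block.k != 1 or block.groups != 1:
        raise ValueError("sa_forward requires a block with k=1 and groups=1")
    return _apply(block, x)
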