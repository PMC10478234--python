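"""The dense-residual / contextual-attention 3-D U-Net and its ablation variants.

Architecture (default four levels, channel width doubling per level):

* encoder: one configurable block per level; 2x2x2 max-pooling after the
  first three levels, the deepest level only extracts features;
* skip connections: identity, plain self-attention, or the local contextual
  attention block, applied to each encoder output before the decoder reuses
  it;
* decoder: three stages.  With an attention skip, stage ``i`` concatenates
  [attention(enc_i), enc_i, upsample(dec_{i+1})]; with identity skips it
  concatenates [enc_i, upsample(dec_{i+1})].  A pointwise fusion convolution
  brings the concatenation back to the stage width before the configured
  block runs, so block widths are identical across skip variants and the
  parameter cost of attention is independent of the block choice;
* heads: the full-resolution decoder output goes through a pointwise
  convolution and channel softmax.  With deep supervision enabled, the two
  deeper decoder stages and the bottleneck each get their own head whose
  probabilities are trilinearly upsampled to the input size (four supervised
  outputs in total).

Upsampling between decoder stages is a kernel-2 stride-2 transposed
convolution.  Class prediction is the argmax over the two-class softmax, with
exact ties resolving to background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concat, maxpool2, resize_trilinear, softmax
from .blocks_dr import DenseResidualBlock, PlainBlock, ResidualBlock
from .blocks_lct import LCTBlock, make_sa_block
from .nn import Conv3d, ConvTranspose2, Module

__all__ = ["NetworkConfig", "ForwardOutput", "DRLCTUNet", "build", "forward",
           "count_params", "make_variant", "VARIANTS"]

_BLOCKS = {
    "plain": PlainBlock,
    "residual": ResidualBlock,
    "dense_residual": DenseResidualBlock,
}

_SKIPS = ("identity", "self_attention", "lct")


@dataclass(frozen=True)
class NetworkConfig:
    levels: int = 4
    base_channels: int = 16
    block: str = "dense_residual"
    skip: str = "lct"
    lct_k: int = 3
    lct_groups: int = 4
    in_channels: int = 1
    n_classes: int = 2
    deep_supervision: bool = True
    norm: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if self.block not in _BLOCKS:
            raise ValueError(f"unknown block {self.block!r}; choose from {sorted(_BLOCKS)}")
        if self.skip not in _SKIPS:
            raise ValueError(f"unknown skip {self.skip!r}; choose from {_SKIPS}")
        if self.skip == "lct":
            for i in range(self.levels):
                width = self.base_channels * 2**i
                if width % self.lct_groups:
                    raise ValueError(
                        f"lct_groups={self.lct_groups} does not divide level width {width}"
                    )

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.levels)]


@dataclass
class ForwardOutput:
    """Softmax class probabilities: main full-resolution output plus any
    deep-supervision auxiliaries (all upsampled to the input size)."""

    main: object
    aux: list


class DRLCTUNet(Module):
    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ch = config.channels
        block_cls = _BLOCKS[config.block]
        norm = config.norm

        ins = [config.in_channels] + ch[:-1]
        self.encoders = [
            block_cls(ins[i], ch[i], norm=norm, rng=rng, dtype=dtype)
            for i in range(config.levels)
        ]
        n_dec = config.levels - 1
        self.ups = [
            ConvTranspose2(ch[i + 1], ch[i], rng=rng, dtype=dtype) for i in range(n_dec)
        ]
        if config.skip == "identity":
            self.skips = [None] * n_dec
            parts = 2
        else:
            maker = (
                (lambda c: make_sa_block(c, rng=rng, dtype=dtype))
                if config.skip == "self_attention"
                else (lambda c: LCTBlock(c, k=config.lct_k, groups=config.lct_groups,
                                         rng=rng, dtype=dtype))
            )
            self.skips = [maker(ch[i]) for i in range(n_dec)]
            parts = 3
        self.fuses = [
            Conv3d(parts * ch[i], ch[i], k=1, rng=rng, dtype=dtype)
            for i in range(n_dec)
        ]
        self.decoders = [
            block_cls(ch[i], ch[i], norm=norm, rng=rng, dtype=dtype)
            for i in range(n_dec)
        ]
        self.main_head = Conv3d(ch[0], config.n_classes, k=1, rng=rng, dtype=dtype)
        if config.deep_supervision:
            # heads on the two deeper decoder stages and the bottleneck
            self.aux_heads = [
                Conv3d(ch[i], config.n_classes, k=1, rng=rng, dtype=dtype)
                for i in list(range(1, n_dec)) + [config.levels - 1]
            ]
        else:
            self.aux_heads = []

    def forward(self, x: Tensor) -> ForwardOutput:
        cfg = self.config
        factor = 2 ** (cfg.levels - 1)
        _, _, d, h, w = x.shape
        if h % factor or w % factor or d % factor:
            raise ValueError(
                f"spatial dims {(d, h, w)} must be divisible by {factor}"
            )
        feats = []
        cur = x
        for i, enc in enumerate(self.encoders):
            cur = enc(cur)
            feats.append(cur)
            if i < cfg.levels - 1:
                cur = maxpool2(cur)
        dec = feats[-1]
        dec_feats: dict[int, Tensor] = {}
        for i in reversed(range(cfg.levels - 1)):
            up = self.ups[i](dec)
            if self.skips[i] is None:
                parts = [feats[i], up]
            else:
                parts = [self.skips[i](feats[i]), feats[i], up]
            fused = self.fuses[i](concat(parts, axis=1))
            dec = self.decoders[i](fused)
            dec_feats[i] = dec
        main = softmax(self.main_head(dec_feats[0]), axis=1)
        aux = []
        if cfg.deep_supervision:
            sources = [dec_feats[i] for i in range(1, cfg.levels - 1)] + [feats[-1]]
            for head, src in zip(self.aux_heads, sources):
                p = softmax(head(src), axis=1)
                aux.append(resize_trilinear(p, (d, h, w)))
        return ForwardOutput(main, aux)


def build(config: NetworkConfig, seed: int = 0, dtype=np.float32) -> DRLCTUNet:
    """Construct the network; weight initialisation is seeded and layer order
    is fixed, so two builds from the same config and seed are identical."""
    return DRLCTUNet(config, seed=seed, dtype=dtype)


def forward(net: DRLCTUNet, x: np.ndarray) -> ForwardOutput:
    """Run a (C, D, H, W) block through the network, returning numpy outputs."""
    x = np.asarray(x, dtype=net.dtype)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError(f"expected (C, D, H, W) input, got shape {x.shape}")
    out = net(Tensor(x[None]))
    return ForwardOutput(out.main.data[0], [a.data[0] for a in out.aux])


def count_params(net: DRLCTUNet) -> int:
    """Total number of trainable scalars."""
    return int(sum(p.size for p in net.parameters()))


VARIANTS = {
    "unet": dict(block="plain", skip="identity"),
    "sa": dict(block="plain", skip="self_attention"),
    "lct": dict(block="plain", skip="lct"),
    "r": dict(block="residual", skip="identity"),
    "dr": dict(block="dense_residual", skip="identity"),
    "dr_lct": dict(block="dense_residual", skip="lct"),
}


def make_variant(name: str, **overrides) -> NetworkConfig:
    """Config for an ablation row: unet, sa, lct, r, dr or dr_lct."""
    if name not in VARIANTS:
        raise KeyError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    return NetworkConfig(**{**VARIANTS[name], **overrides})
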