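"""Neural-network layers on top of the :mod:`corovox._autograd` engine."""

from __future__ import annotations

import numpy as np

from ._autograd import (
    Tensor,
    batch_norm,
    conv3d,
    conv_transpose2,
    relu,
)

__all__ = ["Module", "Conv3d", "ConvTranspose2", "BatchNorm3d", "ConvUnit", "Adam"]


class Module:
    """Base class: recursive parameter/buffer discovery and train/eval mode."""

    training: bool = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(value, dict) and name == "_buffers":
                for k, v in value.items():
                    yield f"{prefix}{k}", v

    def apply(self, fn):
        fn(self)
        for value in vars(self).values():
            if isinstance(value, Module):
                value.apply(fn)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.apply(fn)
        return self

    def train(self, mode: bool = True):
        return self.apply(lambda m: setattr(m, "training", mode))

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{n}": p.data for n, p in self.named_parameters()}
        state.update({f"buffer.{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                params[name].data[...] = value
            elif kind == "buffer":
                buffers[name][...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """Stride-1 'same'-padded (grouped) 3-D convolution."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        k: int = 3,
        groups: int = 1,
        bias: bool = True,
        pad_mode: str = "zeros",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if k % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {k}")
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"groups={groups} must divide channels ({in_channels}->{out_channels})"
            )
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * k**3
        std = np.sqrt(2.0 / fan_in)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = k
        self.groups = groups
        self.pad_mode = pad_mode
        shape = (out_channels, in_channels // groups, k, k, k)
        self.w = Tensor(rng.normal(0.0, std, shape).astype(dtype), requires_grad=True)
        self.b = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        return conv3d(x, self.w, self.b, groups=self.groups, pad_mode=self.pad_mode)


class ConvTranspose2(Module):
    """Kernel-2 stride-2 transposed convolution (doubles D, H, W)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_channels * 8))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = Tensor(
            rng.normal(0.0, std, (in_channels, out_channels, 2, 2, 2)).astype(dtype),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2(x, self.w, self.b)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float64),
            "running_var": np.ones(channels, dtype=np.float64),
        }

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(
            x,
            self.gamma,
            self.beta,
            self._buffers["running_mean"],
            self._buffers["running_var"],
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class ConvUnit(Module):
    """3x3x3 convolution, optional batch normalisation, then ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        k: int = 3,
        norm: bool = False,
        pad_mode: str = "zeros",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        self.conv = Conv3d(
            in_channels, out_channels, k=k, pad_mode=pad_mode, rng=rng, dtype=dtype
        )
        self.norm = BatchNorm3d(out_channels, dtype=dtype) if norm else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        return relu(y)

    @classmethod
    def identity(cls, channels: int, k: int = 3, dtype=np.float64) -> "ConvUnit":
        """Unit whose convolution is the identity (centre-one kernel, zero bias).

        On non-negative input the whole unit is then the identity map, which
        makes block algebra exactly checkable.
        """
        unit = cls(channels, channels, k=k, norm=False, dtype=dtype)
        unit.conv.w.data[...] = 0.0
        c = k // 2
        for ch in range(channels):
            unit.conv.w.data[ch, ch, c, c, c] = 1.0
        unit.conv.b.data[...] = 0.0
        return unit


class Adam(Module):
    """Adam optimiser with L2 weight decay folded into the gradient."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= (self.lr * update).astype(p.data.dtype)
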