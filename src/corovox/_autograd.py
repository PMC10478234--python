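"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the segmentation network needs: elementwise
arithmetic, reductions, ReLU, channel softmax, concatenation, stride-1 "same"
3-D (grouped) convolution, 2x max pooling, kernel-2/stride-2 transposed
convolution, trilinear resizing and batch normalisation.  Tensors carry a
``requires_grad`` flag; calling :meth:`Tensor.backward` on a scalar result
accumulates gradients into every reachable parameter.

All heavy kernels are expressed through ``sliding_window_view`` + matmul or
``einsum`` so that a single BLAS-backed contraction does the work.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "softmax",
    "concat",
    "conv3d",
    "conv_transpose2",
    "maxpool2",
    "resize_trilinear",
    "batch_norm",
]


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(
            self, other, np.multiply, lambda g, a, b: (g * b.data, g * a.data)
        )

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other, like=self) - self

    def __neg__(self):
        return _unary(self, lambda d: -d, lambda g, d: -g)

    def __truediv__(self, other):
        return _binary(
            self,
            other,
            np.divide,
            lambda g, a, b: (g / b.data, -g * a.data / (b.data * b.data)),
        )

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return _unary(self, lambda d: d**e, lambda g, d: g * e * d ** (e - 1.0))

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad)
        if self.requires_grad:
            out._parents = (self,)

            def _bw(node=out, parent=self, idx=idx):
                # basic (slice/int) indexing only: no duplicated positions
                g = np.zeros_like(parent.data)
                g[idx] += node.grad
                _acc(parent, g)

            out._backward = _bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if self.requires_grad:
            out._parents = (self,)

            def _bw(node=out, parent=self, axis=axis, keepdims=keepdims):
                g = node.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                _acc(parent, np.broadcast_to(g, parent.data.shape))

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        if self.requires_grad:
            out._parents = (self,)

            def _bw(node=out, parent=self):
                _acc(parent, node.grad.reshape(parent.data.shape))

            out._backward = _bw
        return out


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


def _acc(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(np.asarray(g), t.data.shape)
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _unary(x: Tensor, fwd, bwd) -> Tensor:
    out = Tensor(fwd(x.data), x.requires_grad)
    if x.requires_grad:
        out._parents = (x,)

        def _bw(node=out, parent=x):
            _acc(parent, bwd(node.grad, parent.data))

        out._backward = _bw
    return out


def _binary(a, b, fwd, bwd) -> Tensor:
    a = as_tensor(a, like=b if isinstance(b, Tensor) else None)
    b = as_tensor(b, like=a)
    out = Tensor(fwd(a.data, b.data), a.requires_grad or b.requires_grad)
    if out.requires_grad:
        out._parents = (a, b)

        def _bw(node=out, a=a, b=b):
            ga, gb = bwd(node.grad, a, b)
            _acc(a, ga)
            _acc(b, gb)

        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# pointwise non-linearities


def relu(x: Tensor) -> Tensor:
    return _unary(x, lambda d: np.maximum(d, 0), lambda g, d: g * (d > 0))


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad)
    if x.requires_grad:
        out._parents = (x,)

        def _bw(node=out, parent=x, y=y, axis=axis):
            g = node.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            _acc(parent, y * (g - dot))

        out._backward = _bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
    )
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]

        def _bw(node=out, parents=tensors, sizes=sizes, axis=axis):
            splits = np.cumsum(sizes[:-1])
            for p, g in zip(parents, np.split(node.grad, splits, axis=axis)):
                _acc(p, g)

        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# convolution


def _conv3d_raw(x: np.ndarray, w: np.ndarray, groups: int, pad_mode: str) -> np.ndarray:
    """Stride-1 'same' correlation of (N,C,D,H,W) with (Cout,C/g,k,k,k)."""
    n, c, d, h, wd = x.shape
    cout, cg, k = w.shape[0], w.shape[1], w.shape[2]
    p = k // 2
    if p:
        mode = "wrap" if pad_mode == "circular" else "constant"
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), mode=mode)
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))  # N,C,D,H,W,k,k,k
    og = cout // groups
    out = np.empty((n, d, h, wd, cout), dtype=x.dtype)
    for g in range(groups):
        cols = (
            win[:, g * cg : (g + 1) * cg]
            .transpose(0, 2, 3, 4, 1, 5, 6, 7)
            .reshape(n, d, h, wd, cg * k * k * k)
        )
        wg = w[g * og : (g + 1) * og].reshape(og, -1)
        out[..., g * og : (g + 1) * og] = cols @ wg.T
    return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))


def _conv3d_dw(x, go, wshape, groups: int, pad_mode: str) -> np.ndarray:
    n, c, d, h, wd = x.shape
    cout, cg, k = wshape[0], wshape[1], wshape[2]
    p = k // 2
    if p:
        mode = "wrap" if pad_mode == "circular" else "constant"
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), mode=mode)
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    og = cout // groups
    dw = np.empty(wshape, dtype=x.dtype)
    for g in range(groups):
        cols = (
            win[:, g * cg : (g + 1) * cg]
            .transpose(0, 2, 3, 4, 1, 5, 6, 7)
            .reshape(-1, cg * k * k * k)
        )
        gog = go[:, g * og : (g + 1) * og].transpose(0, 2, 3, 4, 1).reshape(-1, og)
        dw[g * og : (g + 1) * og] = (gog.T @ cols).reshape(og, cg, k, k, k)
    return dw


def _conv3d_wt(w: np.ndarray, groups: int) -> np.ndarray:
    """Weights of the adjoint convolution: per-group transpose + spatial flip."""
    cout, cg, k = w.shape[0], w.shape[1], w.shape[2]
    og = cout // groups
    w5 = w.reshape(groups, og, cg, k, k, k)
    wt = w5.transpose(0, 2, 1, 3, 4, 5)[..., ::-1, ::-1, ::-1]
    return np.ascontiguousarray(wt).reshape(groups * cg, og, k, k, k)


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    groups: int = 1,
    pad_mode: str = "zeros",
) -> Tensor:
    data = _conv3d_raw(x.data, w.data, groups, pad_mode)
    if b is not None:
        data += b.data.reshape(1, -1, 1, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(data, req)
    if req:
        out._parents = (x, w) + ((b,) if b is not None else ())

        def _bw(node=out, x=x, w=w, b=b, groups=groups, pad_mode=pad_mode):
            go = node.grad
            if x.requires_grad:
                _acc(x, _conv3d_raw(go, _conv3d_wt(w.data, groups), groups, pad_mode))
            if w.requires_grad:
                _acc(w, _conv3d_dw(x.data, go, w.data.shape, groups, pad_mode))
            if b is not None and b.requires_grad:
                _acc(b, go.sum(axis=(0, 2, 3, 4)))

        out._backward = _bw
    return out


def conv_transpose2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2: doubles every spatial dim.

    ``w`` has shape (Cin, Cout, 2, 2, 2); non-overlapping output windows make
    the operation a single einsum.
    """
    n, c, d, h, wd = x.shape
    cout = w.shape[1]
    out6 = np.einsum("ncdhw,coijl->nodihjwl", x.data, w.data)
    data = np.ascontiguousarray(out6).reshape(n, cout, 2 * d, 2 * h, 2 * wd)
    if b is not None:
        data += b.data.reshape(1, -1, 1, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(data, req)
    if req:
        out._parents = (x, w) + ((b,) if b is not None else ())

        def _bw(node=out, x=x, w=w, b=b, dims=(n, cout, d, h, wd)):
            n_, cout_, d_, h_, wd_ = dims
            go6 = node.grad.reshape(n_, cout_, d_, 2, h_, 2, wd_, 2)
            if x.requires_grad:
                _acc(x, np.einsum("nodihjwl,coijl->ncdhw", go6, w.data))
            if w.requires_grad:
                _acc(w, np.einsum("ncdhw,nodihjwl->coijl", x.data, go6))
            if b is not None and b.requires_grad:
                _acc(b, node.grad.sum(axis=(0, 2, 3, 4)))

        out._backward = _bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
    xr = (
        x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(n, c, d // 2, h // 2, w // 2, 8)
    )
    idx = xr.argmax(axis=-1)
    data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(data, x.requires_grad)
    if x.requires_grad:
        out._parents = (x,)

        def _bw(node=out, parent=x, idx=idx, dims=(n, c, d, h, w)):
            n_, c_, d_, h_, w_ = dims
            g8 = np.zeros((n_, c_, d_ // 2, h_ // 2, w_ // 2, 8), dtype=node.grad.dtype)
            np.put_along_axis(g8, idx[..., None], node.grad[..., None], axis=-1)
            g = (
                g8.reshape(n_, c_, d_ // 2, h_ // 2, w_ // 2, 2, 2, 2)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(n_, c_, d_, h_, w_)
            )
            _acc(parent, g)

        out._backward = _bw
    return out


def _axis_plan(n_in: int, n_out: int):
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    f = np.floor(pos)
    t = pos - f
    i0 = np.clip(f.astype(int), 0, n_in - 1)
    i1 = np.clip(f.astype(int) + 1, 0, n_in - 1)
    return i0, i1, t


def resize_trilinear(x: Tensor, out_spatial: tuple[int, int, int]) -> Tensor:
    """Linear resampling of the three trailing axes (half-pixel-centred)."""
    plans = []
    y = x.data
    for axis, n_out in zip((2, 3, 4), out_spatial):
        n_in = y.shape[axis]
        if n_in == n_out:
            plans.append(None)
            continue
        i0, i1, t = _axis_plan(n_in, n_out)
        tb = t.reshape((-1,) + (1,) * (y.ndim - axis - 1))
        y = np.take(y, i0, axis=axis) * (1.0 - tb) + np.take(y, i1, axis=axis) * tb
        plans.append((n_in, i0, i1, t))
    y = y.astype(x.dtype, copy=False)
    out = Tensor(y, x.requires_grad)
    if x.requires_grad:
        out._parents = (x,)

        def _bw(node=out, parent=x, plans=plans):
            g = node.grad
            for axis, plan in zip((4, 3, 2), reversed(plans)):
                if plan is None:
                    continue
                n_in, i0, i1, t = plan
                gm = np.moveaxis(g, axis, 0)
                acc = np.zeros((n_in,) + gm.shape[1:], dtype=g.dtype)
                tb = t.reshape((-1,) + (1,) * (gm.ndim - 1))
                np.add.at(acc, i0, gm * (1.0 - tb))
                np.add.at(acc, i1, gm * tb)
                g = np.moveaxis(acc, 0, axis)
            _acc(parent, g)

        out._backward = _bw
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel normalisation over (N, D, H, W); updates running stats in place."""
    axes = (0, 2, 3, 4)
    cshape = (1, -1, 1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(cshape)) * inv_std.reshape(cshape)
    data = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    out = Tensor(data.astype(x.dtype, copy=False), req)
    if req:
        out._parents = (x, gamma, beta)
        nn = x.data.size // x.data.shape[1]

        def _bw(node=out, x=x, gamma=gamma, beta=beta, xhat=xhat, inv_std=inv_std,
                training=training, nn=nn):
            go = node.grad
            if gamma.requires_grad:
                _acc(gamma, (go * xhat).sum(axis=(0, 2, 3, 4)))
            if beta.requires_grad:
                _acc(beta, go.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                gx = go * gamma.data.reshape(1, -1, 1, 1, 1)
                if training:
                    s1 = gx.sum(axis=(0, 2, 3, 4), keepdims=True)
                    s2 = (gx * xhat).sum(axis=(0, 2, 3, 4), keepdims=True)
                    dx = (gx - s1 / nn - xhat * s2 / nn) * inv_std.reshape(1, -1, 1, 1, 1)
                else:
                    dx = gx * inv_std.reshape(1, -1, 1, 1, 1)
                _acc(x, dx)

        out._backward = _bw
    return out
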