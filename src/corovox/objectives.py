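"""Dice loss, the deep-supervision composite loss, and training schedules.

The loss for a supervised output is the soft Dice loss

    L = 1 - (2 * sum(p * g) + s) / (sum(p) + sum(g) + s)

with a small smoothing constant ``s`` so empty masks stay well defined.  With
deep supervision the total is ``L1 + alpha * (L2 + L3 + L4)`` where L1 is the
full-resolution output's loss and L2..L4 belong to the auxiliary heads; the
weight ``alpha`` shrinks on a fixed epoch schedule so late training is driven
by the final output alone.

The default schedules implement the full-scale training recipe: 180 epochs,
learning rate 1e-5 / 1e-6 / 1e-7 on epochs [0,100) / [100,160) / [160,180],
alpha = 0.8^floor(epoch/40) stepping at epochs 40, 80, 120 and 160, weight
decay 5e-4, batch size 3.  ``ScheduleConfig.scaled`` compresses the epoch
boundaries proportionally for short desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor

__all__ = ["ScheduleConfig", "LossBundle", "dice_loss", "deep_supervision_loss",
           "alpha_at_epoch", "lr_at_epoch"]

Piece = tuple[tuple[float, float], float]  # ((epoch_lo, epoch_hi), value)

_LR_PIECES: tuple[Piece, ...] = (
    ((0, 100), 1e-5),
    ((100, 160), 1e-6),
    ((160, 180), 1e-7),
)
_ALPHA_PIECES: tuple[Piece, ...] = (
    ((0, 40), 1.0),
    ((40, 80), 0.8),
    ((80, 120), 0.8**2),
    ((120, 160), 0.8**3),
    ((160, 180), 0.8**4),
)


@dataclass(frozen=True)
class ScheduleConfig:
    """Piecewise learning-rate and deep-supervision-weight schedules.

    Intervals are half-open [lo, hi) except the last, which includes its
    upper boundary (the final epoch).
    """

    lr_pieces: tuple[Piece, ...] = _LR_PIECES
    alpha_pieces: tuple[Piece, ...] = _ALPHA_PIECES
    weight_decay: float = 5e-4
    epochs: int = 180
    batch_size: int = 3

    def __post_init__(self):
        for pieces in (self.lr_pieces, self.alpha_pieces):
            if pieces[0][0][0] != 0 or pieces[-1][0][1] != self.epochs:
                raise ValueError("schedule pieces must span [0, epochs]")
            for (a, b), v in pieces:
                if b <= a or v <= 0:
                    raise ValueError(f"bad schedule piece (({a},{b}), {v})")

    def scaled(self, epochs: int,
               lr_values: tuple[float, ...] | None = None) -> "ScheduleConfig":
        """Compress epoch boundaries proportionally to a shorter run.

        ``lr_values`` optionally replaces the per-piece learning rates (the
        full-scale rates suit a 180-epoch GPU run, not a short desk run).
        """
        f = epochs / self.epochs

        def rescale(pieces, values=None):
            out = []
            for i, ((a, b), v) in enumerate(pieces):
                lo = int(round(a * f))
                hi = int(round(b * f)) if i < len(pieces) - 1 else epochs
                if values is not None:
                    v = values[i]
                if hi > lo:
                    out.append(((lo, hi), v))
            # re-chain boundaries in case rounding collapsed a piece
            chained = []
            prev = 0
            for (lo, hi), v in out:
                chained.append(((prev, hi), v))
                prev = hi
            return tuple(chained)

        return ScheduleConfig(
            lr_pieces=rescale(self.lr_pieces, lr_values),
            alpha_pieces=rescale(self.alpha_pieces),
            weight_decay=self.weight_decay,
            epochs=epochs,
            batch_size=self.batch_size,
        )


@dataclass
class LossBundle:
    """The four supervised losses of one step and their weighted total."""

    l1: float
    l2: float = 0.0
    l3: float = 0.0
    l4: float = 0.0
    alpha: float = 1.0

    @property
    def total(self) -> float:
        return self.l1 + self.alpha * (self.l2 + self.l3 + self.l4)


def dice_loss(pred, gt, smooth: float = 1e-5):
    """Soft Dice loss; accepts numpy arrays or autodiff tensors for ``pred``.

    ``pred`` holds foreground probabilities in [0, 1]; ``gt`` is a binary
    mask of the same shape.
    """
    gt = np.asarray(gt.voxels if hasattr(gt, "voxels") else gt)
    pred_shape = pred.shape
    if tuple(pred_shape) != gt.shape:
        raise ValueError(f"shape mismatch: pred {tuple(pred_shape)} vs gt {gt.shape}")
    if not isinstance(pred, Tensor):
        pred = np.asarray(pred)
        if pred.size and (pred.min() < -1e-6 or pred.max() > 1 + 1e-6):
            raise ValueError("pred must contain probabilities in [0, 1]")
    gt = gt.astype(pred.dtype if isinstance(pred, np.ndarray) else np.float64)
    inter = (pred * gt).sum()
    total = pred.sum() + gt.sum()
    return 1.0 - (2.0 * inter + smooth) / (total + smooth)


def deep_supervision_loss(l1, l2, l3, l4, alpha: float):
    """Composite loss L1 + alpha * (L2 + L3 + L4)."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    for name, l in (("l1", l1), ("l2", l2), ("l3", l3), ("l4", l4)):
        if not isinstance(l, Tensor) and l < 0:
            raise ValueError(f"{name} must be non-negative, got {l}")
    return l1 + alpha * (l2 + l3 + l4)


def _lookup(epoch: int, pieces: tuple[Piece, ...], epochs: int) -> float:
    if not (0 <= epoch <= epochs):
        raise ValueError(f"epoch {epoch} outside [0, {epochs}]")
    for i, ((lo, hi), value) in enumerate(pieces):
        last = i == len(pieces) - 1
        if lo <= epoch < hi or (last and epoch == hi):
            return value
    raise ValueError(f"epoch {epoch} not covered by schedule")  # pragma: no cover


def alpha_at_epoch(epoch: int, sched: ScheduleConfig | None = None) -> float:
    """Deep-supervision weight in force at ``epoch``."""
    sched = sched or ScheduleConfig()
    return _lookup(epoch, sched.alpha_pieces, sched.epochs)


def lr_at_epoch(epoch: int, sched: ScheduleConfig | None = None) -> float:
    """Learning rate in force at ``epoch``."""
    sched = sched or ScheduleConfig()
    return _lookup(epoch, sched.lr_pieces, sched.epochs)
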