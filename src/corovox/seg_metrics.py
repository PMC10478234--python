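"""Voxel-overlap and surface-distance evaluation metrics.

Overlap metrics come from the confusion counts of two binary masks:

    DSC = 2TP / (2TP + FN + FP)     Recall = TP / (TP + FN)
    Precision = TP / (TP + FP)

Surface distances operate on the boundary voxel sets (foreground voxels with
at least one 6-neighbour that is background or outside the grid):

    ASSD = (sum_a min_b ||a-b|| + sum_b min_a ||a-b||) / (|Sp| + |Sg|)
    HD   = max(max_a min_b ||a-b||, max_b min_a ||a-b||)

Distances are Euclidean, in voxel units by default; passing a spacing scales
each axis to millimetres first.  Degenerate inputs (empty ground truth or
empty prediction) raise :class:`UndefinedMetricError` rather than returning a
sentinel, so aggregate statistics cannot silently absorb them.

Nearest-neighbour queries use a KD-tree; on small instances the result is
identical to brute-force all-pairs evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .imaging_io import LabelMask

__all__ = ["ConfusionCounts", "SurfaceSet", "MetricsReport", "UndefinedMetricError",
           "confusion", "dsc", "recall", "precision", "extract_surface", "assd",
           "hausdorff", "evaluate_case"]


class UndefinedMetricError(ValueError):
    """A metric's denominator (or a surface set) is empty."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass
class SurfaceSet:
    """Boundary voxel coordinates of a mask, optionally scaled to mm."""

    coords: np.ndarray  # (n, 3) float
    spacing: tuple[float, float, float] | None = None

    def __len__(self) -> int:
        return len(self.coords)

    def scaled(self) -> np.ndarray:
        if self.spacing is None:
            return self.coords
        return self.coords * np.asarray(self.spacing)


@dataclass
class MetricsReport:
    """The five evaluation metrics of one prediction/reference pair.

    Fields are ``None`` when undefined (empty prediction or reference).
    ``units`` records whether distances are in voxels or mm.
    """

    dsc: float | None
    recall: float | None
    precision: float | None
    assd: float | None
    hd: float | None
    units: str = "voxel"


def _as_bool(mask) -> np.ndarray:
    data = mask.voxels if isinstance(mask, LabelMask) else np.asarray(mask)
    return data.astype(bool)


def confusion(pred, gt) -> ConfusionCounts:
    """Voxelwise TP/FP/FN counts of a predicted vs reference mask."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return ConfusionCounts(
        tp=int((p & g).sum()), fp=int((p & ~g).sum()), fn=int((~p & g).sum())
    )


def dsc(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        raise UndefinedMetricError("DSC undefined: both masks empty")
    return 2 * c.tp / denom


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: empty ground truth")
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: empty prediction")
    return c.tp / (c.tp + c.fp)


def extract_surface(mask, spacing=None) -> SurfaceSet:
    """Foreground voxels with at least one background-or-outside 6-neighbour."""
    m = _as_bool(mask)
    padded = np.pad(m, 1, mode="constant")
    interior = np.ones_like(m)
    for ax in range(3):
        lo = np.take(padded, range(0, m.shape[ax]), axis=ax)
        hi = np.take(padded, range(2, m.shape[ax] + 2), axis=ax)
        # realign the padded slabs with the unpadded mask on the other axes
        other = [a for a in range(3) if a != ax]
        sl = [slice(1, -1)] * 3
        sl[ax] = slice(None)
        lo = lo[tuple(sl)]
        hi = hi[tuple(sl)]
        interior &= lo & hi
    surface = m & ~interior
    return SurfaceSet(np.argwhere(surface).astype(float), spacing)


def _directed_sums(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    da = cKDTree(b).query(a, k=1)[0]
    db = cKDTree(a).query(b, k=1)[0]
    return da, db


def assd(sp: SurfaceSet, sg: SurfaceSet) -> float:
    """Average symmetric surface distance between two boundary sets."""
    if len(sp) == 0 or len(sg) == 0:
        raise UndefinedMetricError("ASSD undefined: empty surface set")
    da, db = _directed_sums(sp.scaled(), sg.scaled())
    return float((da.sum() + db.sum()) / (len(sp) + len(sg)))


def hausdorff(sp: SurfaceSet, sg: SurfaceSet) -> float:
    """Symmetric Hausdorff distance between two boundary sets."""
    if len(sp) == 0 or len(sg) == 0:
        raise UndefinedMetricError("Hausdorff undefined: empty surface set")
    da, db = _directed_sums(sp.scaled(), sg.scaled())
    return float(max(da.max(), db.max()))


def evaluate_case(pred, gt, spacing=None) -> MetricsReport:
    """All five metrics for one mask pair; undefined metrics become ``None``."""
    c = confusion(pred, gt)

    def guard(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetricError:
            return None

    sp = extract_surface(pred, spacing)
    sg = extract_surface(gt, spacing)
    return MetricsReport(
        dsc=guard(dsc, c),
        recall=guard(recall, c),
        precision=guard(precision, c),
        assd=guard(assd, sp, sg),
        hd=guard(hausdorff, sp, sg),
        units="mm" if spacing is not None else "voxel",
    )
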