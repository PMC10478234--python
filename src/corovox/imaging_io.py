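"""Volume I/O, Hounsfield-unit windowing and depth-block planning.

CT angiography volumes are HU-valued 3-D grids stored as NIfTI.  Before
segmentation the HU range is clamped to a fixed window — [−260, 760] HU, a
range that brackets contrast-enhanced coronary blood while discarding air and
dense bone — and rescaled linearly to [0, 1].  Because the network consumes
fixed-depth slabs (16 slices by default), long volumes are cut into
overlapping blocks whose predictions are averaged back together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "LabelMask",
    "NormalizedVolume",
    "BlockPlan",
    "DimensionalityError",
    "HeaderError",
    "HU_WINDOW",
    "read_volume",
    "read_mask",
    "write_volume",
    "window_and_normalize",
    "plan_blocks",
    "extract_blocks",
    "stitch_blocks",
]

#: Default HU clamp window applied before normalisation.
HU_WINDOW = (-260.0, 760.0)


class DimensionalityError(ValueError):
    """The on-disk image is not a 3-D scalar grid."""


class HeaderError(IOError):
    """The NIfTI header could not be parsed."""


@dataclass
class CTVolume:
    """A HU-valued scalar grid indexed (slice, row, col) with mm spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.45, 0.4, 0.4)
    affine: np.ndarray | None = None
    header: object = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise DimensionalityError(
                f"expected a 3-D grid, got shape {self.voxels.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelMask:
    """Binary foreground mask on the same lattice as its volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.45, 0.4, 0.4)
    affine: np.ndarray | None = None
    header: object = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D mask, got shape {self.voxels.shape}"
            )
        values = np.unique(self.voxels)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {values[:10]}")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class NormalizedVolume:
    """Windowed volume rescaled to [0, 1]."""

    voxels: np.ndarray
    window: tuple[float, float] = HU_WINDOW
    spacing: tuple[float, float, float] = (0.45, 0.4, 0.4)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BlockPlan:
    """Slab decomposition of a volume along the slice axis."""

    depth: int
    block_depth: int = 16
    stride: int = 8
    starts: list[int] = field(default_factory=list)
    pad_to: int = 0  # padded depth when depth < block_depth, else 0


def read_volume(path: str | Path) -> CTVolume:
    """Read a 3-D NIfTI scalar image, keeping HU values and header metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        header = img.header.copy()
        zooms = header.get_zooms()
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several parse-error types
        raise HeaderError(f"could not read NIfTI header of {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path} is {data.ndim}-D, expected 3-D")
    spacing = tuple(float(z) for z in zooms[:3])
    return CTVolume(
        voxels=data, spacing=spacing, affine=img.affine.copy(), header=header
    )


def read_mask(path: str | Path) -> LabelMask:
    vol = read_volume(path)
    return LabelMask(vol.voxels, vol.spacing, vol.affine, vol.header)


def write_volume(vol: CTVolume | LabelMask | NormalizedVolume, path: str | Path) -> None:
    """Write a volume/mask as NIfTI; readable back voxel-identically."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = vol.voxels
    affine = getattr(vol, "affine", None)
    header = getattr(vol, "header", None)
    if affine is None:
        affine = np.diag(list(vol.spacing) + [1.0])
    if isinstance(vol, LabelMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine, header=header)
    if header is None:
        img.header.set_zooms(vol.spacing)
    nib.save(img, path)


def window_and_normalize(
    vol: CTVolume, lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1]
) -> NormalizedVolume:
    """Clamp HU values to [lo, hi] and rescale linearly to [0, 1]."""
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got ({lo}, {hi})")
    scaled = (np.clip(vol.voxels, lo, hi) - lo) / (hi - lo)
    return NormalizedVolume(
        voxels=scaled.astype(np.float32), window=(lo, hi), spacing=vol.spacing
    )


def plan_blocks(depth: int, block_depth: int = 16, stride: int = 8) -> BlockPlan:
    """Plan fixed-depth slabs covering every slice.

    Starts advance by ``stride``; the final start is clamped so the last block
    ends exactly at the volume end.  Volumes shallower than ``block_depth``
    yield a single block with replicate padding at the end.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if block_depth < 1 or stride < 1:
        raise ValueError("block_depth and stride must be positive")
    if stride > block_depth:
        raise ValueError(f"stride {stride} may not exceed block_depth {block_depth}")
    if depth < block_depth:
        return BlockPlan(depth, block_depth, stride, starts=[0], pad_to=block_depth)
    starts: list[int] = []
    s = 0
    while True:
        if s + block_depth >= depth:
            last = depth - block_depth
            if not starts or last > starts[-1]:
                starts.append(last)
            break
        starts.append(s)
        s += stride
    return BlockPlan(depth, block_depth, stride, starts=starts)


def extract_blocks(volume: np.ndarray, plan: BlockPlan) -> list[np.ndarray]:
    """Cut (D, H, W) data into the planned slabs (replicate-padding if needed)."""
    data = volume
    if plan.pad_to:
        pad = plan.pad_to - data.shape[0]
        data = np.concatenate([data, np.repeat(data[-1:], pad, axis=0)], axis=0)
    return [data[s : s + plan.block_depth] for s in plan.starts]


def stitch_blocks(plan: BlockPlan, block_outputs: list[np.ndarray]) -> np.ndarray:
    """Average per-block class-probability slabs back into a full volume.

    Overlapping slices get the arithmetic mean of every contributing block;
    replicate-padded slices are discarded.
    """
    if len(block_outputs) != len(plan.starts):
        raise ValueError(
            f"expected {len(plan.starts)} block outputs, got {len(block_outputs)}"
        )
    first = np.asarray(block_outputs[0])
    n_classes = first.shape[0]
    full_depth = plan.pad_to or plan.depth
    spatial = first.shape[2:]
    acc = np.zeros((n_classes, full_depth) + spatial, dtype=np.float64)
    count = np.zeros(full_depth, dtype=np.int64)
    for start, block in zip(plan.starts, block_outputs):
        block = np.asarray(block)
        if block.shape != (n_classes, plan.block_depth) + spatial:
            raise ValueError(
                f"block at start {start} has shape {block.shape}, expected "
                f"{(n_classes, plan.block_depth) + spatial}"
            )
        acc[:, start : start + plan.block_depth] += block
        count[start : start + plan.block_depth] += 1
    acc /= count[None, :, None, None]
    return acc[:, : plan.depth]
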