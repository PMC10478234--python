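"""Synthetic CCTA-like vascular phantoms with ground-truth tubular masks.

The generator emulates the properties that make coronary segmentation hard:

* a small tubular foreground (well under 5% of voxels) arranged as a
  bifurcating tree whose radius shrinks geometrically with every branching
  generation;
* contrast-enhanced vessel intensities that fall off linearly toward the
  distal tips, mimicking uneven contrast-medium distribution;
* a nearby bright distractor tube (vein/aorta-like) that is *not* part of the
  label, so an intensity threshold alone cannot solve the task;
* additive Gaussian HU noise.

One integer seed drives independent sub-streams for topology, branch angles,
distractor placement and noise, so e.g. switching noise off does not change
the geometry.  The same :class:`PhantomSpec` always produces bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .imaging_io import CTVolume, LabelMask, write_volume

__all__ = ["PhantomSpec", "Segment", "sample_tree", "rasterize_mask",
           "render_volume", "generate_case"]


@dataclass(frozen=True)
class PhantomSpec:
    """Seeded parameterisation of the synthetic vascular tree generator."""

    seed: int = 0
    shape: tuple[int, int, int] = (32, 64, 64)
    n_trees: int = 2
    max_bifurcations: int = 3
    root_radius: float = 2.2
    radius_decay: float = 0.72
    segment_length: tuple[float, float] = (8.0, 14.0)
    branch_angle_sd: float = 0.35
    vessel_hu: float = 350.0
    distal_contrast_drop: float = 0.4
    background_hu: float = 40.0
    distractor: bool = True
    distractor_hu: float = 300.0
    distractor_radius: float = 3.0
    noise_sd: float = 20.0
    spacing: tuple[float, float, float] = (0.45, 0.4, 0.4)

    def __post_init__(self):
        if min(self.shape) < 8:
            raise ValueError(f"shape components must be >= 8, got {self.shape}")
        if self.root_radius <= 0:
            raise ValueError("root_radius must be positive")
        if not (0.0 < self.radius_decay < 1.0):
            raise ValueError("radius_decay must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 <= self.distal_contrast_drop <= 1.0):
            raise ValueError("distal_contrast_drop must lie in [0, 1]")


@dataclass
class Segment:
    """A straight centerline piece sampled at ~1-voxel steps."""

    points: np.ndarray        # (M, 3) float coordinates, (slice, row, col)
    radius: float             # constant tube radius of this piece
    arc: np.ndarray           # (M,) arc length from the tree root, in voxels
    tree: int                 # index of the owning tree
    generation: int           # 0 = root piece


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _perpendicular(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        v -= v.dot(d) * d
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _grow(start, direction, length, shape, margin):
    """March in ~unit steps, reflecting off the (margin-inset) volume walls."""
    pts = [np.asarray(start, dtype=float)]
    d = _unit(np.asarray(direction, dtype=float))
    n_steps = max(int(round(length)), 1)
    lo = np.full(3, margin)
    hi = np.asarray(shape, dtype=float) - 1.0 - margin
    for _ in range(n_steps):
        nxt = pts[-1] + d
        for ax in range(3):
            if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                d[ax] = -d[ax]
                nxt = pts[-1] + d
        pts.append(np.clip(nxt, lo, hi))
    return np.array(pts), d


def sample_tree(spec: PhantomSpec) -> list[Segment]:
    """Sample the bifurcating centerline tree(s) for a phantom.

    Each bifurcation spawns two children whose radius is the parent radius
    times ``radius_decay`` and whose directions are the parent direction tilted
    by angles drawn around ``branch_angle_sd``.  All points stay inside the
    volume.  Deterministic for a fixed spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    topo_ss, angle_ss, _, _ = ss.spawn(4)
    rng_topo = np.random.default_rng(topo_ss)
    rng_angle = np.random.default_rng(angle_ss)
    shape = np.asarray(spec.shape, dtype=float)
    margin = spec.root_radius + 1.0
    segments: list[Segment] = []

    for tree_idx in range(spec.n_trees):
        start = rng_topo.uniform(margin, shape - 1.0 - margin)
        direction = _unit(rng_topo.normal(size=3))
        # (start point, direction, radius, arc offset, generation)
        frontier = [(start, direction, spec.root_radius, 0.0, 0)]
        while frontier:
            p0, d0, radius, arc0, gen = frontier.pop()
            length = rng_topo.uniform(*spec.segment_length)
            pts, d_end = _grow(p0, d0, length, spec.shape, min(margin, radius + 1.0))
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            arc = arc0 + np.concatenate([[0.0], np.cumsum(steps)])
            segments.append(Segment(pts, radius, arc, tree_idx, gen))
            if gen < spec.max_bifurcations:
                perp = _perpendicular(d_end, rng_angle)
                for sign in (1.0, -1.0):
                    angle = abs(rng_angle.normal(spec.branch_angle_sd,
                                                 spec.branch_angle_sd / 2.0))
                    child_dir = _unit(np.cos(angle) * d_end
                                      + np.sin(angle) * sign * perp)
                    frontier.append(
                        (pts[-1].copy(), child_dir, radius * spec.radius_decay,
                         float(arc[-1]), gen + 1)
                    )
    return segments


def _stamp_capsules(shape, segments_xyz_r, mask):
    """OR into ``mask`` all voxels whose center lies within radius of a segment."""
    dims = np.asarray(shape)
    for p0, p1, r in segments_xyz_r:
        lo = np.maximum(np.floor(np.minimum(p0, p1) - r).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + r).astype(int) + 1, dims)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        pts = np.stack([zz, yy, xx], axis=-1).astype(float)
        seg = p1 - p0
        seg_len2 = seg.dot(seg)
        if seg_len2 == 0.0:
            dist = np.linalg.norm(pts - p0, axis=-1)
        else:
            t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
            nearest = p0 + t[..., None] * seg
            dist = np.linalg.norm(pts - nearest, axis=-1)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= dist <= r


def rasterize_mask(tree: list[Segment], shape: tuple[int, int, int]) -> LabelMask:
    """Union of radius-``r`` capsules swept along every centerline piece.

    A voxel is foreground iff its center lies within the local radius of the
    centerline (no partial-volume weighting).
    """
    mask = np.zeros(shape, dtype=bool)
    pieces = []
    for seg in tree:
        for a, b in zip(seg.points[:-1], seg.points[1:]):
            pieces.append((a, b, seg.radius))
        if len(seg.points) == 1:
            pieces.append((seg.points[0], seg.points[0], seg.radius))
    _stamp_capsules(shape, pieces, mask)
    return LabelMask(mask.astype(np.uint8))


def _distractor_path(spec: PhantomSpec, rng: np.random.Generator):
    """A straight bright tube spanning the widest axis of the volume."""
    shape = np.asarray(spec.shape, dtype=float)
    axis = int(np.argmax(shape))
    r = min(spec.distractor_radius, (min(spec.shape) - 4.0) / 2.0)
    p0 = rng.uniform(r + 1.0, np.maximum(shape - r - 2.0, r + 1.0 + 1e-6))
    p1 = p0.copy()
    p0[axis] = r + 1.0
    p1[axis] = shape[axis] - r - 2.0
    jitter = rng.normal(0.0, 2.0, size=3)
    jitter[axis] = 0.0
    p1 += jitter
    p1 = np.clip(p1, r + 1.0, shape - r - 2.0)
    return p0, p1


def _distractor_mask(spec: PhantomSpec, vessel_mask: np.ndarray) -> np.ndarray:
    """Rejection-sample a distractor tube that never overlaps the labeled tree."""
    _, _, _, distr_ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng = np.random.default_rng(distr_ss)
    # the tube must fit the volume; shrink it for very small phantoms
    radius = min(spec.distractor_radius, (min(spec.shape) - 4.0) / 2.0)
    if radius < 0.8:
        return np.zeros(spec.shape, dtype=bool)
    for attempt in range(40):
        p0, p1 = _distractor_path(spec, rng)
        cand = np.zeros(spec.shape, dtype=bool)
        _stamp_capsules(spec.shape, [(p0, p1, radius)], cand)
        if not (cand & vessel_mask).any() and cand.any():
            return cand
        if attempt and attempt % 10 == 0 and radius > 1.0:
            radius *= 0.8  # narrow the tube if the volume is crowded
    return np.zeros(spec.shape, dtype=bool)


def render_volume(spec: PhantomSpec, tree: list[Segment], mask: LabelMask) -> CTVolume:
    """Render HU intensities for a rasterized tree.

    Vessel voxels get ``vessel_hu`` attenuated linearly toward the distal tips
    by ``distal_contrast_drop`` (intensity at normalized arc length t is
    ``vessel_hu * (1 - drop * t)``); the optional distractor tube is rendered
    at ``distractor_hu`` but stays out of the label; everything else is
    ``background_hu`` plus zero-mean Gaussian noise.
    """
    _, _, noise_ss, _ = np.random.SeedSequence(spec.seed).spawn(4)
    vol = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    fg = mask.voxels.astype(bool)

    if fg.any() and tree:
        samples = np.concatenate([seg.points for seg in tree], axis=0)
        arcs = np.concatenate([seg.arc for seg in tree])
        tree_ids = np.concatenate(
            [np.full(len(seg.points), seg.tree) for seg in tree]
        )
        max_arc = np.zeros(int(tree_ids.max()) + 1)
        for t in range(len(max_arc)):
            sel = tree_ids == t
            if sel.any():
                max_arc[t] = max(arcs[sel].max(), 1e-9)
        norm_arc = arcs / max_arc[tree_ids]
        kdt = cKDTree(samples)
        coords = np.argwhere(fg).astype(float)
        _, idx = kdt.query(coords, k=1)
        t_norm = norm_arc[idx]
        vol[fg] = spec.vessel_hu * (1.0 - spec.distal_contrast_drop * t_norm)

    if spec.distractor:
        distr = _distractor_mask(spec, fg)
        vol[distr & ~fg] = spec.distractor_hu

    if spec.noise_sd > 0:
        rng_noise = np.random.default_rng(noise_ss)
        vol += rng_noise.normal(0.0, spec.noise_sd, size=spec.shape)

    return CTVolume(vol.astype(np.float32), spacing=spec.spacing)


def generate_case(
    spec: PhantomSpec, out_dir: str | Path | None = None, stem: str = "case"
) -> tuple[CTVolume, LabelMask]:
    """Sample, rasterize and render one phantom; optionally write a NIfTI pair."""
    tree = sample_tree(spec)
    mask = rasterize_mask(tree, spec.shape)
    mask = LabelMask(mask.voxels, spacing=spec.spacing)
    vol = render_volume(spec, tree, mask)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(vol, out_dir / f"{stem}_image.nii.gz")
        write_volume(mask, out_dir / f"{stem}_label.nii.gz")
    return vol, mask


def case_specs(base: PhantomSpec, n: int, seed: int) -> list[PhantomSpec]:
    """Derive ``n`` per-case specs with independent seeds from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [
        replace(base, seed=int(c.generate_state(1)[0] % (2**31))) for c in children
    ]
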