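"""Overlap and surface-distance metrics against brute-force oracles."""

import numpy as np
import pytest

from corovox.seg_metrics import (
    ConfusionCounts,
    SurfaceSet,
    UndefinedMetricError,
    assd,
    confusion,
    dsc,
    evaluate_case,
    extract_surface,
    hausdorff,
    precision,
    recall,
)
from conftest import random_mask


def brute_force_surface(mask):
    coords = []
    d, h, w = mask.shape
    for z in range(d):
        for y in range(h):
            for x in range(w):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (0 <= zz < d and 0 <= yy < h and 0 <= xx < w) or not mask[zz, yy, xx]:
                        coords.append((z, y, x))
                        break
    return set(coords)


def brute_force_distances(a, b):
    da = [min(np.linalg.norm(p - q) for q in b) for p in a]
    db = [min(np.linalg.norm(p - q) for q in a) for p in b]
    return da, db


class TestConfusion:
    def test_identical_masks(self, rng):
        m = random_mask(rng, (6, 6, 6))
        c = confusion(m, m)
        assert (c.tp, c.fp, c.fn) == (int(m.sum()), 0, 0)

    def test_two_element_enumeration(self):
        gt = np.zeros((2, 2, 2), dtype=np.uint8)
        pred = np.zeros((2, 2, 2), dtype=np.uint8)
        gt[0, 0, 0] = gt[0, 0, 1] = 1       # {a, b}
        pred[0, 0, 1] = pred[1, 1, 1] = 1   # {b, c}
        c = confusion(pred, gt)
        assert (c.tp, c.fp, c.fn) == (1, 1, 1)

    def test_matches_triple_loop_count(self, rng):
        p, g = random_mask(rng, (8, 8, 8)), random_mask(rng, (8, 8, 8))
        c = confusion(p, g)
        tp = fp = fn = 0
        for z in range(8):
            for y in range(8):
                for x in range(8):
                    tp += p[z, y, x] and g[z, y, x]
                    fp += p[z, y, x] and not g[z, y, x]
                    fn += (not p[z, y, x]) and g[z, y, x]
        assert (c.tp, c.fp, c.fn) == (tp, fp, fn)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))


class TestOverlapMetrics:
    def test_one_one_one(self):
        c = ConfusionCounts(1, 1, 1)
        assert dsc(c) == pytest.approx(0.5)
        assert recall(c) == pytest.approx(0.5)
        assert precision(c) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        c = ConfusionCounts(tp=3, fp=1, fn=2)
        assert dsc(c) == pytest.approx(6 / 9)
        assert recall(c) == pytest.approx(0.6)
        assert precision(c) == pytest.approx(0.75)

    def test_perfect_prediction(self):
        c = ConfusionCounts(5, 0, 0)
        assert dsc(c) == recall(c) == precision(c) == 1.0

    def test_empty_cases_raise_typed_error(self):
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(0, 3, 0))
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(0, 0, 3))
        with pytest.raises(UndefinedMetricError):
            dsc(ConfusionCounts(0, 0, 0))

    def test_dsc_is_harmonic_mean_of_recall_precision(self, rng):
        for _ in range(100):
            tp = int(rng.integers(1, 50))
            fp = int(rng.integers(0, 50))
            fn = int(rng.integers(0, 50))
            c = ConfusionCounts(tp, fp, fn)
            r, p = recall(c), precision(c)
            assert dsc(c) == pytest.approx(2 * r * p / (r + p))


class TestSurfaceExtraction:
    def test_solid_cube_surface(self):
        m = np.zeros((5, 5, 5), dtype=np.uint8)
        m[1:4, 1:4, 1:4] = 1
        surf = extract_surface(m)
        assert len(surf) == 26  # all 27 but the centre

    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        m[1, 1, 1] = 1
        surf = extract_surface(m)
        np.testing.assert_array_equal(surf.coords, [[1, 1, 1]])

    def test_thin_line_all_surface(self):
        m = np.zeros((8, 3, 3), dtype=np.uint8)
        m[:, 1, 1] = 1
        assert len(extract_surface(m)) == 8

    def test_volume_edge_counts_as_background(self):
        m = np.ones((2, 2, 2), dtype=np.uint8)
        assert len(extract_surface(m)) == 8

    def test_matches_brute_force_rule(self, rng):
        m = random_mask(rng, (7, 7, 7), p=0.35)
        fast = {tuple(int(v) for v in c) for c in extract_surface(m).coords}
        assert fast == brute_force_surface(m)


class TestSurfaceDistances:
    def test_identical_surfaces_zero(self, rng):
        m = random_mask(rng, (6, 6, 6))
        s = extract_surface(m)
        assert assd(s, s) == 0.0
        assert hausdorff(s, s) == 0.0

    def test_single_pair(self):
        sp = SurfaceSet(np.array([[0.0, 0.0, 0.0]]))
        sg = SurfaceSet(np.array([[3.0, 0.0, 0.0]]))
        assert assd(sp, sg) == pytest.approx(3.0)
        assert hausdorff(sp, sg) == pytest.approx(3.0)

    def test_hand_worked_asymmetric_case(self):
        sp = SurfaceSet(np.array([[0.0, 0.0, 0.0]]))
        sg = SurfaceSet(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 4.0]]))
        # ASSD = (0 + (0 + 4)) / (1 + 2), HD = max over directed maxima
        assert assd(sp, sg) == pytest.approx(4.0 / 3.0)
        assert hausdorff(sp, sg) == pytest.approx(4.0)

    def test_empty_surface_raises(self):
        empty = SurfaceSet(np.zeros((0, 3)))
        nonempty = SurfaceSet(np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(UndefinedMetricError):
            assd(empty, nonempty)
        with pytest.raises(UndefinedMetricError):
            hausdorff(nonempty, empty)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            a = extract_surface(random_mask(rng, (12, 12, 12)))
            b = extract_surface(random_mask(rng, (12, 12, 12)))
            da, db = brute_force_distances(a.coords, b.coords)
            expected_assd = (sum(da) + sum(db)) / (len(a) + len(b))
            expected_hd = max(max(da), max(db))
            assert assd(a, b) == pytest.approx(expected_assd, abs=1e-9)
            assert hausdorff(a, b) == pytest.approx(expected_hd, abs=1e-9)

    def test_symmetry_and_assd_le_hausdorff(self, rng):
        a = extract_surface(random_mask(rng, (10, 10, 10)))
        b = extract_surface(random_mask(rng, (10, 10, 10)))
        assert assd(a, b) == pytest.approx(assd(b, a))
        assert hausdorff(a, b) == pytest.approx(hausdorff(b, a))
        assert assd(a, b) <= hausdorff(a, b) + 1e-12

    def test_spacing_scales_distances(self):
        sp = SurfaceSet(np.array([[0.0, 0.0, 0.0]]), spacing=(2.0, 1.0, 1.0))
        sg = SurfaceSet(np.array([[3.0, 0.0, 0.0]]), spacing=(2.0, 1.0, 1.0))
        assert hausdorff(sp, sg) == pytest.approx(6.0)


class TestEvaluateCase:
    def test_perfect_prediction(self, rng):
        m = random_mask(rng, (8, 8, 8))
        rep = evaluate_case(m, m)
        assert (rep.dsc, rep.recall, rep.precision) == (1.0, 1.0, 1.0)
        assert rep.assd == 0.0 and rep.hd == 0.0

    def test_disjoint_masks_zero_dsc(self):
        p = np.zeros((6, 6, 6), dtype=np.uint8)
        g = np.zeros((6, 6, 6), dtype=np.uint8)
        p[0, 0, 0] = 1
        g[5, 5, 5] = 1
        rep = evaluate_case(p, g)
        assert rep.dsc == 0.0

    def test_empty_prediction_yields_missing_fields_not_crash(self, rng):
        g = random_mask(rng, (6, 6, 6))
        rep = evaluate_case(np.zeros((6, 6, 6), dtype=np.uint8), g)
        assert rep.precision is None and rep.assd is None and rep.hd is None
        assert rep.dsc == 0.0 and rep.recall == 0.0

    def test_translation_invariance(self, rng):
        p = random_mask(rng, (8, 8, 8), p=0.25)
        g = random_mask(rng, (8, 8, 8), p=0.25)
        big_p = np.zeros((12, 12, 12), dtype=np.uint8)
        big_g = np.zeros((12, 12, 12), dtype=np.uint8)
        big_p[1:9, 1:9, 1:9] = p
        big_g[1:9, 1:9, 1:9] = g
        shift_p = np.roll(big_p, (2, 1, 3), axis=(0, 1, 2))
        shift_g = np.roll(big_g, (2, 1, 3), axis=(0, 1, 2))
        r1 = evaluate_case(big_p, big_g)
        r2 = evaluate_case(shift_p, shift_g)
        for f in ("dsc", "recall", "precision", "assd", "hd"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f), abs=1e-9)

    def test_whole_report_against_independent_script(self, rng):
        """Field-wise agreement with a self-contained re-implementation."""
        from corovox.phantom_gen import PhantomSpec, generate_case

        _, gt = generate_case(PhantomSpec(seed=11, shape=(12, 16, 16),
                                          n_trees=1, max_bifurcations=1,
                                          root_radius=1.5,
                                          segment_length=(4.0, 6.0)))
        pred = np.roll(gt.voxels, 1, axis=2)  # imperfect but overlapping
        rep = evaluate_case(pred, gt)
        p, g = pred.astype(bool), gt.voxels.astype(bool)
        tp = (p & g).sum(); fp = (p & ~g).sum(); fn = (~p & g).sum()
        sp = np.array(sorted(brute_force_surface(p)), dtype=float)
        sg = np.array(sorted(brute_force_surface(g)), dtype=float)
        da, db = brute_force_distances(sp, sg)
        assert rep.dsc == pytest.approx(2 * tp / (2 * tp + fn + fp))
        assert rep.recall == pytest.approx(tp / (tp + fn))
        assert rep.precision == pytest.approx(tp / (tp + fp))
        assert rep.assd == pytest.approx((sum(da) + sum(db)) / (len(sp) + len(sg)))
        assert rep.hd == pytest.approx(max(max(da), max(db)))
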