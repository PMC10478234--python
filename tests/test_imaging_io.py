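"""Volume I/O round trips, HU windowing and block planning/stitching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corovox.imaging_io import (
    CTVolume,
    DimensionalityError,
    LabelMask,
    extract_blocks,
    plan_blocks,
    read_mask,
    read_volume,
    stitch_blocks,
    window_and_normalize,
    write_volume,
)


class TestRoundTrip:
    def test_volume_round_trip_identity(self, small_volume, tmp_path):
        path = tmp_path / "vol.nii.gz"
        write_volume(small_volume, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.voxels, small_volume.voxels)
        assert back.spacing == pytest.approx(small_volume.spacing)

    def test_mask_round_trip(self, rng, tmp_path):
        mask = LabelMask((rng.random((8, 8, 8)) < 0.3).astype(np.uint8))
        path = tmp_path / "mask.nii.gz"
        write_volume(mask, path)
        back = read_mask(path)
        np.testing.assert_array_equal(back.voxels, mask.voxels)
        assert back.voxels.dtype == np.uint8

    def test_slice_interval_spacing_survives(self, rng, tmp_path):
        vol = CTVolume(rng.normal(size=(8, 8, 8)), spacing=(0.45, 0.4, 0.4))
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        assert read_volume(path).spacing == pytest.approx((0.45, 0.4, 0.4))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_4d_image_rejected(self, rng, tmp_path):
        import nibabel as nib

        path = tmp_path / "4d.nii.gz"
        nib.save(nib.Nifti1Image(rng.random((4, 4, 4, 2)), np.eye(4)), path)
        with pytest.raises(DimensionalityError):
            read_volume(path)

    def test_unwritable_path_raises(self, small_volume, tmp_path):
        with pytest.raises(FileNotFoundError):
            write_volume(small_volume, tmp_path / "missing_dir" / "v.nii.gz")

    def test_phantom_case_round_trips(self, tmp_path):
        from corovox.phantom_gen import PhantomSpec, generate_case

        vol, mask = generate_case(PhantomSpec(seed=3, shape=(16, 24, 24)))
        write_volume(vol, tmp_path / "img.nii.gz")
        write_volume(mask, tmp_path / "lab.nii.gz")
        np.testing.assert_array_equal(read_volume(tmp_path / "img.nii.gz").voxels, vol.voxels)
        np.testing.assert_array_equal(read_mask(tmp_path / "lab.nii.gz").voxels, mask.voxels)


class TestWindowing:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-500.0, 0.0), (1000.0, 1.0), (250.0, 0.5), (-260.0, 0.0), (760.0, 1.0)],
    )
    def test_window_values(self, hu, expected):
        vol = CTVolume(np.full((1, 1, 1), hu))
        out = window_and_normalize(vol)
        assert out.voxels[0, 0, 0] == pytest.approx(expected, abs=1e-6)

    def test_output_in_unit_interval(self, small_volume):
        out = window_and_normalize(small_volume)
        assert out.voxels.min() >= 0.0 and out.voxels.max() <= 1.0
        assert out.voxels.shape == small_volume.voxels.shape

    def test_monotone_in_hu(self, rng):
        hu = np.sort(rng.normal(0, 400, size=64))
        out = window_and_normalize(CTVolume(hu.reshape(4, 4, 4)))
        flat = out.voxels.reshape(-1)
        assert (np.diff(flat) >= -1e-7).all()

    def test_invalid_window_rejected(self, small_volume):
        with pytest.raises(ValueError):
            window_and_normalize(small_volume, lo=100.0, hi=100.0)


class TestBlockPlanning:
    @pytest.mark.parametrize(
        "depth,block,stride,starts",
        [
            (40, 16, 8, [0, 8, 16, 24]),
            (16, 16, 8, [0]),
            (20, 16, 8, [0, 4]),
            (17, 16, 8, [0, 1]),
            (8, 16, 8, [0]),
        ],
    )
    def test_start_positions(self, depth, block, stride, starts):
        assert plan_blocks(depth, block, stride).starts == starts

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            plan_blocks(10, block_depth=0)
        with pytest.raises(ValueError):
            plan_blocks(10, block_depth=8, stride=0)
        with pytest.raises(ValueError):
            plan_blocks(10, block_depth=8, stride=9)

    @given(depth=st.integers(1, 64), stride=st.integers(1, 16))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_every_slice_covered(self, depth, stride):
        block = 16
        stride = min(stride, block)
        plan = plan_blocks(depth, block, stride)
        covered = np.zeros(max(depth, plan.pad_to or depth), dtype=int)
        for s in plan.starts:
            covered[s : s + block] += 1
        assert (covered[:depth] >= 1).all()
        assert plan.starts == sorted(set(plan.starts))


class TestStitching:
    def test_non_overlapping_is_concatenation(self, rng):
        plan = plan_blocks(32, 16, 16)
        blocks = [rng.random((2, 16, 4, 4)) for _ in plan.starts]
        out = stitch_blocks(plan, blocks)
        np.testing.assert_allclose(out, np.concatenate(blocks, axis=1))

    def test_overlap_takes_mean(self):
        plan = plan_blocks(24, 16, 8)
        b0 = np.full((2, 16, 2, 2), 0.2)
        b1 = np.full((2, 16, 2, 2), 0.6)
        out = stitch_blocks(plan, [b0, b1])
        np.testing.assert_allclose(out[:, 8:16], 0.4)
        np.testing.assert_allclose(out[:, :8], 0.2)
        np.testing.assert_allclose(out[:, 16:], 0.6)

    def test_matches_accumulate_and_divide_oracle(self, rng):
        plan = plan_blocks(37, 16, 5)
        blocks = [rng.random((2, 16, 3, 3)) for _ in plan.starts]
        out = stitch_blocks(plan, blocks)
        acc = np.zeros((2, 37, 3, 3))
        cnt = np.zeros(37)
        for s, b in zip(plan.starts, blocks):
            acc[:, s : s + 16] += b
            cnt[s : s + 16] += 1
        np.testing.assert_allclose(out, acc / cnt[None, :, None, None], atol=1e-12)

    def test_padded_slices_discarded(self, rng):
        plan = plan_blocks(10, 16, 8)
        out = stitch_blocks(plan, [rng.random((2, 16, 2, 2))])
        assert out.shape == (2, 10, 2, 2)

    def test_shape_mismatch_rejected(self, rng):
        plan = plan_blocks(24, 16, 8)
        with pytest.raises(ValueError):
            stitch_blocks(plan, [rng.random((2, 16, 2, 2))])
        with pytest.raises(ValueError):
            stitch_blocks(plan, [rng.random((2, 8, 2, 2))] * 2)

    def test_constant_field_preserved(self):
        plan = plan_blocks(29, 16, 8)
        blocks = [np.full((2, 16, 2, 2), 0.75) for _ in plan.starts]
        np.testing.assert_allclose(stitch_blocks(plan, blocks), 0.75)

    def test_extract_blocks_replicate_pads(self, rng):
        data = rng.random((10, 2, 2))
        plan = plan_blocks(10, 16, 8)
        blocks = extract_blocks(data, plan)
        assert blocks[0].shape == (16, 2, 2)
        np.testing.assert_array_equal(blocks[0][10:], np.repeat(data[-1:], 6, axis=0))
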