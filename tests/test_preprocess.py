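"""Normalisation, box derivation, cropping and resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meniscus3d.preprocess import (Box3D, NormalizationStats, box_from_mask,
                                   crop_to_rois, fit_stats, minmax_normalize,
                                   resample_trilinear, standardize,
                                   training_crop_shape, union_extent_voxels)


class TestMinMaxAndStandardize:
    def test_three_value_example(self):
        img = np.array([[[10.0, 20.0, 30.0]]])
        assert np.allclose(minmax_normalize(img), [[[0.0, 0.5, 1.0]]])

    def test_already_unit_range_unchanged(self):
        img = np.random.default_rng(0).random((4, 4, 4))
        img.flat[0], img.flat[1] = 0.0, 1.0
        assert np.allclose(minmax_normalize(img), img, atol=1e-7)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.full((3, 3, 3), 7.0))

    def test_standardize_worked_value_and_round_trip(self):
        stats = NormalizationStats(mu=0.5, sigma=0.25)
        assert standardize(np.array([1.0]), stats)[0] == pytest.approx(2.0)
        img = np.random.default_rng(1).random((5, 5, 5)).astype(np.float32)
        back = standardize(img, stats) * stats.sigma + stats.mu
        assert np.allclose(back, img, atol=1e-6)
        assert np.allclose(standardize(np.full((3,), stats.mu), stats), 0.0)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            NormalizationStats(mu=0.0, sigma=0.0)


class TestFitStats:
    def test_single_volume_binary_values(self):
        stats = fit_stats([np.array([0.0, 1.0])])
        assert stats.mu == pytest.approx(0.5)
        assert stats.sigma == pytest.approx(0.5)  # population sd

    def test_duplicated_volume_changes_nothing(self):
        v = np.random.default_rng(2).random((4, 4))
        one = fit_stats([v])
        two = fit_stats([v, v.copy()])
        assert one.mu == pytest.approx(two.mu)
        assert one.sigma == pytest.approx(two.sigma)

    def test_matches_flatten_and_pool_oracle(self, rng):
        vols = [rng.random((3, 4, 5)) for _ in range(4)]
        stats = fit_stats(vols)
        pooled = np.concatenate([v.ravel() for v in vols])
        assert stats.mu == pytest.approx(pooled.mean(), rel=1e-12)
        assert stats.sigma == pytest.approx(pooled.std(), rel=1e-9)

    def test_standardized_cohort_has_unit_pooled_moments(self, rng):
        vols = [minmax_normalize(rng.random((6, 6, 6)) * 100) for _ in range(5)]
        stats = fit_stats(vols)
        z = np.concatenate([standardize(v, stats).ravel() for v in vols])
        assert abs(z.mean()) < 1e-6
        assert abs(z.std() - 1.0) < 1e-5  # float32 pipeline

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fit_stats([])


class TestBoxFromMask:
    def test_worked_example_on_10_cube(self):
        mask = np.zeros((10, 10, 10), dtype=int)
        mask[2:7, 1:6, 0:5] = 1  # index ranges [2,6], [1,5], [0,4]
        box = box_from_mask(mask, 1)
        assert box.center == pytest.approx((0.4, 0.3, 0.2))
        assert box.size == pytest.approx((0.4, 0.4, 0.4))

    def test_single_voxel_structure_has_zero_size(self):
        mask = np.zeros((10, 10, 10), dtype=int)
        mask[3, 4, 5] = 2
        box = box_from_mask(mask, 2)
        assert box.size == (0.0, 0.0, 0.0)
        assert box.center == pytest.approx((0.3, 0.4, 0.5))

    def test_absent_structure_rejected(self):
        with pytest.raises(ValueError):
            box_from_mask(np.zeros((8, 8, 8), dtype=int), 1)

    def test_matches_exhaustive_scan_on_random_blobs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            mask = np.zeros((12, 14, 10), dtype=int)
            n = rng.integers(1, 40)
            idx = (rng.integers(0, 12, n), rng.integers(0, 14, n),
                   rng.integers(0, 10, n))
            mask[idx] = 1
            box = box_from_mask(mask, 1)
            # brute force over every voxel
            lo = np.array([np.inf] * 3)
            hi = -np.array([np.inf] * 3)
            for z in range(12):
                for y in range(14):
                    for x in range(10):
                        if mask[z, y, x] == 1:
                            lo = np.minimum(lo, (z, y, x))
                            hi = np.maximum(hi, (z, y, x))
            n_ax = np.array(mask.shape)
            assert np.allclose(box.center, ((hi - lo) / 2 + lo) / n_ax)
            assert np.allclose(box.size, (hi - lo) / n_ax)


class TestCropAndResample:
    def test_full_grid_crop_is_identity(self, rng):
        img = rng.random((8, 8, 8)).astype(np.float32)
        full = Box3D(center=(0.5, 0.5, 0.5), size=(7 / 8.0,) * 3)
        out = crop_to_rois(img, (full, full), margin=0.0, target_shape=(8, 8, 8))
        assert np.allclose(out, img, atol=1e-6)

    def test_constant_image_stays_constant(self):
        img = np.full((10, 10, 10), 3.25, dtype=np.float32)
        boxes = (Box3D((0.3, 0.3, 0.3), (0.2, 0.2, 0.2)),
                 Box3D((0.7, 0.7, 0.7), (0.2, 0.2, 0.2)))
        out = crop_to_rois(img, boxes, margin=0.05, target_shape=(16, 16, 16))
        assert np.allclose(out, 3.25, atol=1e-6)

    def test_resample_matches_pointwise_trilinear_oracle(self, rng):
        src = rng.random((6, 7, 5)).astype(np.float32)
        tgt_shape = (9, 11, 8)
        out = resample_trilinear(src, tgt_shape)

        def trilinear(vol, p):
            # independent direct implementation
            i0 = np.floor(p).astype(int)
            i1 = np.minimum(i0 + 1, np.array(vol.shape) - 1)
            f = p - i0
            acc = 0.0
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        wz = f[0] if dz else 1 - f[0]
                        wy = f[1] if dy else 1 - f[1]
                        wx = f[2] if dx else 1 - f[2]
                        idx = (i1[0] if dz else i0[0],
                               i1[1] if dy else i0[1],
                               i1[2] if dx else i0[2])
                        acc += wz * wy * wx * vol[idx]
            return acc

        scale = [(s - 1) / (t - 1) for s, t in zip(src.shape, tgt_shape)]
        for _ in range(10):
            t_idx = np.array([rng.integers(0, n) for n in tgt_shape])
            p = t_idx * np.array(scale)
            assert out[tuple(t_idx)] == pytest.approx(trilinear(src, p), abs=1e-5)

    def test_translation_consistent_cropping(self, rng):
        img = rng.random((16, 16, 16)).astype(np.float32)
        mask = np.zeros((16, 16, 16), dtype=int)
        mask[4:8, 5:9, 3:7] = 1
        mask[9:12, 5:9, 3:7] = 2
        boxes = tuple(box_from_mask(mask, s) for s in (1, 2))
        out1 = crop_to_rois(img, boxes, 0.0, (8, 8, 8))
        shift = (2, 1, 3)
        img2 = np.roll(img, shift, axis=(0, 1, 2))
        mask2 = np.roll(mask, shift, axis=(0, 1, 2))
        boxes2 = tuple(box_from_mask(mask2, s) for s in (1, 2))
        out2 = crop_to_rois(img2, boxes2, 0.0, (8, 8, 8))
        assert np.allclose(out1, out2, atol=1e-6)


class TestTrainingCropShape:
    def _pair_with_extent(self, extent, shape):
        # one box whose margined (margin=0) union spans `extent` voxels
        lo = np.zeros(3)
        hi = np.array(extent, dtype=float) - 1  # inclusive indices
        n = np.array(shape, dtype=float)
        center = tuple(((hi - lo) / 2 + lo) / n)
        size = tuple((hi - lo) / n)
        box = Box3D(center, size)
        return (box, box)

    def test_rounding_to_multiples_of_16(self):
        shape = (64, 64, 192)
        pair = self._pair_with_extent((60, 62, 170), shape)
        assert union_extent_voxels(pair, shape, 0.0).tolist() == [60, 62, 170]
        assert training_crop_shape([pair], shape, 0.0) == (64, 64, 176)

    def test_exact_multiples_unchanged(self):
        shape = (64, 64, 64)
        pair = self._pair_with_extent((32, 48, 16), shape)
        assert training_crop_shape([pair], shape, 0.0) == (32, 48, 16)

    def test_tiny_extent_floors_at_16(self):
        shape = (64, 64, 64)
        pair = self._pair_with_extent((7, 7, 7), shape)
        assert training_crop_shape([pair], shape, 0.0) == (16, 16, 16)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            training_crop_shape([], (64, 64, 64), 0.05)


class TestBox3DValidation:
    @given(st.lists(st.floats(0, 1), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_through_array_form(self, values):
        box = Box3D.from_array(values)
        assert np.allclose(box.to_array(), values)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Box3D(center=(1.2, 0.5, 0.5), size=(0.1, 0.1, 0.1))
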