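"""Segmentation, closing, resampling, registration and normalization."""

import numpy as np
import pytest
from scipy import ndimage

from qspect.preprocess import (
    AffineTransform3D,
    BinaryMask3D,
    NormalizationMode,
    apply_transform,
    apply_transform_to_mask,
    dice,
    morphological_closing,
    normalize_spect,
    register_masks_affine,
    resize_spect_to_ct,
    segment_lungs_ct,
    segment_lungs_spect,
)
from qspect.volume_io import Modality, Units, Volume3D

pytestmark = pytest.mark.timeout(600)


def _vol(values, modality=Modality.SPECT, units=Units.COUNTS, spacing=(1, 1, 1)):
    return Volume3D(np.asarray(values, float), spacing, modality, units)


class TestCtSegmentation:
    def test_ellipsoid_phantom_dice(self):
        """-800 HU ellipsoid in a +40 body on air background is recovered."""
        shape = (24, 48, 48)
        zz, yy, xx = np.ogrid[:24, :48, :48]
        ellipsoid = ((zz - 12) / 9) ** 2 + ((yy - 24) / 16) ** 2 + ((xx - 24) / 16) ** 2 <= 1
        ct = np.full(shape, -1024.0)
        body = ((zz - 12) / 12) ** 2 + ((yy - 24) / 22) ** 2 + ((xx - 24) / 22) ** 2 <= 1
        ct[body] = 40.0
        ct[ellipsoid] = -800.0
        mask = segment_lungs_ct(_vol(ct, Modality.CT, Units.HU))
        d = 2 * np.sum(mask.values & ellipsoid) / (mask.count() + ellipsoid.sum())
        assert d >= 0.99

    def test_no_voxel_in_range_errors(self):
        ct = _vol(np.full((4, 4, 4), -1000.0), Modality.CT, Units.HU)
        with pytest.raises(ValueError, match="empty"):
            segment_lungs_ct(ct)

    def test_largest_component_rule(self):
        """Of two in-range blobs only the larger survives (before closing)."""
        ct = np.full((20, 30, 30), 100.0)
        ct[2:10, 2:12, 2:12] = -800.0  # 800 voxels
        ct[12:16, 20:25, 20:25] = -800.0  # 100 voxels
        mask = segment_lungs_ct(_vol(ct, Modality.CT, Units.HU), closing_radius=1)
        assert mask.values[5, 5, 5]
        assert not mask.values[13, 22, 22]


class TestClosing:
    def test_interior_hole_filled_exterior_preserved(self):
        """Brute-force dilate-then-erode oracle on a cube with a hole."""
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[5:25, 5:25, 5:25] = True
        mask[14:17, 14:17, 14:17] = False
        closed = morphological_closing(BinaryMask3D(mask), radius=5)
        from skimage.morphology import ball

        padded = np.pad(mask, 5)
        oracle = ndimage.binary_erosion(
            ndimage.binary_dilation(padded, structure=ball(5)), structure=ball(5)
        )[5:-5, 5:-5, 5:-5]
        assert np.array_equal(closed.values, oracle)
        assert closed.values[15, 15, 15]  # hole filled
        assert closed.values[5:25, 5:25, 5:25].all()

    def test_empty_mask_maps_to_empty(self):
        out = morphological_closing(BinaryMask3D(np.zeros((5, 5, 5), bool)), radius=3)
        assert out.count() == 0

    def test_extensive_and_idempotent(self, rng):
        mask = BinaryMask3D(ndimage.binary_dilation(rng.random((14, 14, 14)) < 0.03, iterations=2))
        once = morphological_closing(mask, radius=2)
        twice = morphological_closing(once, radius=2)
        assert np.all(once.values | ~mask.values)  # output contains input
        assert (once.values & mask.values).sum() == mask.count()
        assert np.array_equal(once.values, twice.values)


class TestSpectSegmentation:
    def test_all_below_threshold_empty(self):
        assert segment_lungs_spect(_vol(np.full((3, 3, 3), 20.0))).count() == 0

    def test_single_voxel_above(self):
        v = np.zeros((3, 3, 3))
        v[1, 1, 1] = 21.0
        mask = segment_lungs_spect(_vol(v))
        assert mask.count() == 1 and mask.values[1, 1, 1]

    def test_matches_elementwise_oracle(self, rng):
        v = rng.uniform(0, 40, size=(6, 6, 6))
        mask = segment_lungs_spect(_vol(v))
        assert np.array_equal(mask.values, v > 20)


class TestResize:
    def test_identity_when_shapes_match(self, rng):
        v = rng.uniform(0, 10, (4, 6, 6))
        ct = _vol(np.full((4, 6, 6), -500.0), Modality.CT, Units.HU)
        out = resize_spect_to_ct(_vol(v), ct)
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_constant_stays_constant(self):
        ct = _vol(np.full((8, 10, 10), -500.0), Modality.CT, Units.HU)
        out = resize_spect_to_ct(_vol(np.full((4, 5, 5), 7.0)), ct)
        np.testing.assert_allclose(out.values, 7.0)

    def test_linear_ramp_interpolates_linearly(self):
        """2 slices (0, 3) to 4 slices: hand-computed values 0, 1, 2, 3."""
        v = np.zeros((2, 3, 3))
        v[1] = 3.0
        ct = _vol(np.full((4, 3, 3), -500.0), Modality.CT, Units.HU)
        out = resize_spect_to_ct(_vol(v), ct)
        np.testing.assert_allclose(out.values[:, 1, 1], [0.0, 1.0, 2.0, 3.0], atol=1e-12)

    def test_single_slice_errors(self):
        ct = _vol(np.full((4, 3, 3), -500.0), Modality.CT, Units.HU)
        with pytest.raises(ValueError, match=">= 2"):
            resize_spect_to_ct(_vol(np.zeros((1, 3, 3))), ct)


def _lung_like_mask(shape=(24, 64, 64)):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    a = ((zz - 12) / 10) ** 2 + ((yy - 32) / 15) ** 2 + ((xx - 20) / 11) ** 2 <= 1
    b = ((zz - 12) / 10) ** 2 + ((yy - 32) / 15) ** 2 + ((xx - 44) / 11) ** 2 <= 1
    return BinaryMask3D(a | b)


class TestRegistration:
    def test_identical_masks_near_identity(self):
        mask = _lung_like_mask()
        tfm = register_masks_affine(mask, mask)
        assert np.linalg.norm(tfm.linear - np.eye(3)) < 0.01
        assert np.linalg.norm(tfm.translation) < 0.1

    def test_translation_recovered(self):
        """A mask shifted by (0, 3, 5) voxels: the resampling transform that
        undoes the shift is the inverse of the applied one."""
        fixed = _lung_like_mask()
        M = AffineTransform3D(np.eye(3), np.array([0.0, 3.0, 5.0]))
        moving = apply_transform_to_mask(fixed, M, fixed.shape)
        tfm = register_masks_affine(moving, fixed)
        np.testing.assert_allclose(tfm.translation, M.inverse().translation, atol=0.5)

    def test_scale_recovered(self):
        fixed = _lung_like_mask()
        center = (np.array(fixed.shape) - 1) / 2
        s = 1.1
        M = AffineTransform3D(np.diag([s, s, s]), center - s * center)
        moving = apply_transform_to_mask(fixed, M, fixed.shape)
        tfm = register_masks_affine(moving, fixed)
        scales = np.diag(tfm.linear)
        np.testing.assert_allclose(scales, np.diag(M.inverse().linear), atol=0.02)

    def test_empty_mask_rejected(self):
        mask = _lung_like_mask()
        with pytest.raises(ValueError, match="empty"):
            register_masks_affine(BinaryMask3D(np.zeros(mask.shape, bool)), mask)


class TestApplyTransform:
    def test_identity_preserves_values(self, rng):
        v = _vol(rng.uniform(0, 5, (5, 6, 7)))
        out = apply_transform(v, AffineTransform3D.identity(), v)
        np.testing.assert_allclose(out.values, v.values, atol=1e-12)

    def test_integer_translation_moves_spike(self):
        v = np.zeros((8, 8, 8))
        v[4, 4, 4] = 9.0
        vol = _vol(v)
        # out(x) = in(x + t): spike appears at 4 - t
        tfm = AffineTransform3D(np.eye(3), np.array([1.0, 2.0, 0.0]))
        out = apply_transform(vol, tfm, vol)
        assert out.values[3, 2, 4] == pytest.approx(9.0)
        assert out.values.sum() == pytest.approx(9.0)

    def test_out_of_grid_zero_fill(self):
        vol = _vol(np.full((4, 4, 4), 5.0))
        tfm = AffineTransform3D(np.eye(3), np.array([10.0, 0.0, 0.0]))
        out = apply_transform(vol, tfm, vol)
        assert np.all(out.values == 0)

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform3D(np.zeros((3, 3)), np.zeros(3))


class TestNormalization:
    def test_max_mode_closed_form(self):
        v = _vol(np.array([0.0, 10.0, 20.0]).reshape(1, 1, 3).repeat(2, axis=0))
        out = normalize_spect(v, NormalizationMode.MAX)
        assert set(np.round(np.unique(out.values), 12)) == {0.0, 0.5, 1.0}

    def test_constant_volume_errors(self):
        v = _vol(np.full((3, 3, 3), 7.0))
        with pytest.raises(ValueError, match="normalize"):
            normalize_spect(v, NormalizationMode.MAX)

    def test_percentile_maps_p99_to_one(self):
        vals = np.arange(1000, dtype=float).reshape(10, 10, 10)
        out = normalize_spect(_vol(vals), NormalizationMode.PERCENTILE99)
        p99 = np.percentile(vals, 99)  # linear interpolation between order stats
        # normalization is affine, so the p99 intensity maps to exactly 1
        # and every voxel above it (the top 1%) exceeds 1 without clipping
        np.testing.assert_allclose((p99 - vals.min()) / (p99 - vals.min()), 1.0)
        above = out.values[vals > p99]
        assert above.size > 0 and np.all(above > 1.0)
        assert out.values.max() > 1.0

    def test_max_mode_in_unit_interval(self, rng):
        for _ in range(100):
            v = _vol(rng.uniform(0, 100, size=(4, 5, 5)))
            out = normalize_spect(v, NormalizationMode.MAX)
            assert out.values.min() == pytest.approx(0.0, abs=1e-15)
            assert out.values.max() == pytest.approx(1.0, abs=1e-15)
            assert np.all((out.values >= 0) & (out.values <= 1 + 1e-15))

    def test_masked_statistics(self, rng):
        """Restricting normalization statistics to a mask changes the scale."""
        vals = rng.uniform(0, 50, size=(4, 5, 5))
        vals[0, 0, 0] = 500.0  # outside the mask
        mask = BinaryMask3D(np.ones(vals.shape, bool))
        mask.values[0, 0, 0] = False
        full = normalize_spect(_vol(vals), NormalizationMode.MAX)
        masked = normalize_spect(_vol(vals), NormalizationMode.MAX, statistics_mask=mask)
        assert masked.values.max() > full.values.max()
        inside = masked.values[mask.values]
        assert inside.max() == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        vals = rng.uniform(10, 50, size=(4, 5, 5))
        for mode in NormalizationMode:
            a = normalize_spect(_vol(vals), mode)
            b = normalize_spect(_vol(vals + 17.0), mode)
            np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_hotspot_robustness_direction(self, rng):
        """A single 50x hotspot voxel barely moves percentile normalization.

        The comparison is over the unaffected lung voxels: the artifact
        inflates the MAX denominator (crushing every lung value) but barely
        shifts the 99th percentile.
        """
        lung = rng.uniform(80, 120, size=(6, 10, 10))
        spot = lung.copy()
        spot[3, 5, 5] = 50 * lung.mean()
        keep = np.ones(lung.shape, dtype=bool)
        keep[3, 5, 5] = False
        deltas = {}
        for mode in NormalizationMode:
            clean = normalize_spect(_vol(lung), mode).values[keep].mean()
            spotted = normalize_spect(_vol(spot), mode).values[keep].mean()
            deltas[mode] = abs(spotted - clean)
        assert deltas[NormalizationMode.MAX] > 10 * deltas[NormalizationMode.PERCENTILE99]
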