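"""Subtraction, mode correction, mucosa threshold, supra-threshold counting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancevol.enhancement_core import (
    AnalysisParams,
    SubtractionMap,
    apply_correction,
    correction_factor,
    enhancement_threshold,
    enhancing_volume,
    quantify,
    subtract,
)
from enhancevol.errors import GridMismatchError, RoiError, ThresholdError
from enhancevol.rois import RegionOfInterest
from enhancevol.volume_io import ImageVolume, VoxelVolume


def _map_from(values_3d, affine=None):
    values_3d = np.asarray(values_3d, dtype=float)
    affine = np.eye(4) if affine is None else affine
    return SubtractionMap(values_3d, (1.0, 1.0, 1.0), affine, np.ones(values_3d.shape, bool))


def _roi(mask, role="normal"):
    return RegionOfInterest(np.asarray(mask, bool), role, np.eye(4))


class TestSubtract:
    def test_elementwise_matches_loop_oracle(self, simple_volume):
        rng = np.random.default_rng(5)
        post = ImageVolume(
            simple_volume.data + rng.normal(0, 20, simple_volume.shape),
            simple_volume.spacing,
            simple_volume.affine,
        )
        sub = subtract(post, simple_volume)
        oracle = np.empty(post.shape)
        for idx in np.ndindex(post.shape):
            oracle[idx] = post.data[idx] - simple_volume.data[idx]
        assert np.array_equal(sub.data, oracle)

    def test_identical_images_give_zero(self, simple_volume):
        assert not subtract(simple_volume, simple_volume).data.any()

    def test_grid_mismatch_rejected(self, simple_volume):
        other_affine = simple_volume.affine.copy()
        other_affine[0, 3] += 2.0
        shifted = ImageVolume(simple_volume.data, simple_volume.spacing, other_affine)
        with pytest.raises(GridMismatchError):
            subtract(simple_volume, shifted)

    def test_invalid_voxels_propagate(self, simple_volume):
        pre = ImageVolume(
            simple_volume.data.copy(), simple_volume.spacing, simple_volume.affine
        )
        pre.valid_mask = np.ones(pre.shape, bool)
        pre.valid_mask[0, 0, 0] = False
        sub = subtract(simple_volume, pre)
        assert not sub.valid_mask[0, 0, 0]
        assert sub.valid_mask.sum() == pre.valid_mask.sum()


class TestCorrectionFactor:
    def test_constant_values_give_that_constant(self):
        data = np.full((10, 10, 2), 7.0)
        c = correction_factor(_map_from(data), _roi(np.ones(data.shape)), 1.0)
        assert abs(c.value - 7.0) <= 0.5  # within half a bin
        assert c.n_voxels == 200

    def test_mode_picks_most_populated_bin(self):
        # 500 zeros, 400 twelves, 100 thirties -> mode 0 (brute-force count)
        values = np.concatenate([np.zeros(500), np.full(400, 12.0), np.full(100, 30.0)])
        data = values.reshape(10, 10, 10)
        c = correction_factor(_map_from(data), _roi(np.ones(data.shape)), 1.0)
        assert c.value == 0.0

    def test_tie_breaks_toward_lower_bin(self):
        values = np.concatenate([np.full(300, 5.0), np.full(300, 9.0)])
        data = values.reshape(10, 10, 6)
        c = correction_factor(_map_from(data), _roi(np.ones(data.shape)), 1.0)
        assert c.value == 5.0

    def test_too_few_voxels_rejected(self):
        data = np.zeros((4, 4, 4))
        mask = np.zeros(data.shape, bool)
        mask[:3, :3, :3] = True  # 27 < 100
        with pytest.raises(RoiError, match="100"):
            correction_factor(_map_from(data), _roi(mask), 1.0)

    def test_wrong_role_rejected(self):
        data = np.zeros((10, 10, 2))
        with pytest.raises(RoiError, match="normal"):
            correction_factor(_map_from(data), _roi(np.ones(data.shape), "tumor"), 1.0)


class TestApplyCorrection:
    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(11)
        data = rng.normal(50, 20, (8, 8, 4))
        mask = rng.random((8, 8, 4)) > 0.5
        sub = _map_from(data)
        from enhancevol.enhancement_core import CorrectionFactor

        c = CorrectionFactor(13.5, 1.0, 500)
        got = apply_correction(sub, _roi(mask, "tumor"), c)
        oracle = sorted(data[idx] - 13.5 for idx in np.ndindex(data.shape) if mask[idx])
        assert np.allclose(np.sort(got), oracle)
        assert got.min() < 0  # negatives retained, not clamped


class TestEnhancementThreshold:
    def test_order_statistic_examples(self):
        values = np.arange(1, 101, dtype=float)
        th = enhancement_threshold(values, 0.05, 0.25)
        assert th.value == pytest.approx(23.75)
        assert th.remaining_max == 95.0
        th40 = enhancement_threshold(values, 0.05, 0.40)
        assert th40.value == pytest.approx(38.0)

    def test_constant_values(self):
        th = enhancement_threshold(np.full(50, 80.0), 0.05, 0.25)
        assert th.value == pytest.approx(20.0)

    @given(
        values=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=300),
        excl=st.floats(0.0, 0.5),
        frac=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_sort_and_trim_oracle(self, values, excl, frac):
        """Independent oracle: explicit descending sort, drop ceil(e*n), take
        fraction of the new maximum."""
        th = enhancement_threshold(np.array(values), excl, frac)
        ordered = sorted(values, reverse=True)
        k = math.ceil(excl * len(values))
        assert th.remaining_max == ordered[k]
        assert th.value == pytest.approx(frac * ordered[k])

    def test_error_cases(self):
        with pytest.raises(ThresholdError, match="empty"):
            enhancement_threshold(np.array([]), 0.05, 0.25)
        with pytest.raises(ThresholdError, match="trim"):
            enhancement_threshold(np.array([1.0, 2.0]), 0.9, 0.25)
        with pytest.raises(ThresholdError, match="no net enhancement"):
            enhancement_threshold(np.array([-5.0, -1.0, -0.5] * 10), 0.05, 0.25)


class TestEnhancingVolume:
    def _setup(self, n_above, shape=(20, 20, 10), spacing=(1.0, 1.0, 1.0)):
        data = np.zeros(shape)
        flat = data.reshape(-1)
        flat[:n_above] = 100.0
        from enhancevol.enhancement_core import CorrectionFactor, EnhancementThreshold

        sub = SubtractionMap(data, spacing, np.diag([*spacing, 1.0]), np.ones(shape, bool))
        tumor = RegionOfInterest(np.ones(shape, bool), "tumor", sub.affine)
        c = CorrectionFactor(0.0, 1.0, 1000)
        th = EnhancementThreshold(50.0, 0.25, 0.05, 200.0, 100)
        return sub, tumor, c, th

    def test_counts_and_volume_at_unit_spacing(self):
        sub, tumor, c, th = self._setup(500)
        res = enhancing_volume(sub, tumor, c, th, VoxelVolume(1.0))
        assert res.voxel_count == 500
        assert res.volume_cm3 == pytest.approx(0.5)

    def test_volume_scales_with_voxel_size(self):
        sub, tumor, c, th = self._setup(2000, spacing=(0.5, 0.5, 2.0))
        res = enhancing_volume(sub, tumor, c, th, VoxelVolume(0.5))
        assert res.volume_cm3 == pytest.approx(1.0)

    def test_zero_enhancing_voxels_is_valid(self):
        sub, tumor, c, th = self._setup(0)
        res = enhancing_volume(sub, tumor, c, th, VoxelVolume(1.0))
        assert res.voxel_count == 0 and res.volume_cm3 == 0.0

    def test_mask_is_subset_of_tumor_roi(self, rim_baseline):
        pre, post, truth, _ = rim_baseline
        res = quantify(
            pre, post, truth.tumor_narrow, truth.normal, truth.mucosa_roi,
            AnalysisParams(skip_registration=True),
        )
        assert not np.any(res.enhancement_mask & ~truth.tumor_narrow.mask)
        assert res.volume_cm3 == pytest.approx(
            res.voxel_count * np.prod(post.spacing) / 1000.0
        )

    def test_strict_vs_inclusive_comparison(self):
        sub, tumor, c, th = self._setup(0)
        sub.data[0, 0, 0] = 50.0  # exactly at the threshold
        assert enhancing_volume(sub, tumor, c, th, VoxelVolume(1.0)).voxel_count == 0
        assert (
            enhancing_volume(sub, tumor, c, th, VoxelVolume(1.0), strict_greater=False).voxel_count
            == 1
        )


class TestQuantifyProperties:
    """Invariances of the full pipeline on the noiseless rim phantom."""

    def test_additive_offset_invariance(self, rim_baseline):
        pre, post, truth, _ = rim_baseline
        params = AnalysisParams(skip_registration=True)
        base = quantify(pre, post, truth.tumor_narrow, truth.normal, truth.mucosa_roi, params)
        post_up = ImageVolume(post.data + 50.0, post.spacing, post.affine)
        pre_up = ImageVolume(pre.data + 30.0, pre.spacing, pre.affine)
        r1 = quantify(pre, post_up, truth.tumor_narrow, truth.normal, truth.mucosa_roi, params)
        r2 = quantify(pre_up, post, truth.tumor_narrow, truth.normal, truth.mucosa_roi, params)
        assert np.array_equal(base.enhancement_mask, r1.enhancement_mask)
        assert np.array_equal(base.enhancement_mask, r2.enhancement_mask)
        assert r1.correction.value == pytest.approx(base.correction.value + 50.0)

    def test_joint_scaling_equivariance(self, rim_baseline):
        pre, post, truth, _ = rim_baseline
        params = AnalysisParams(skip_registration=True)
        base = quantify(pre, post, truth.tumor_narrow, truth.normal, truth.mucosa_roi, params)
        k = 2.0
        scaled = quantify(
            ImageVolume(pre.data * k, pre.spacing, pre.affine),
            ImageVolume(post.data * k, post.spacing, post.affine),
            truth.tumor_narrow, truth.normal, truth.mucosa_roi, params,
        )
        assert np.array_equal(base.enhancement_mask, scaled.enhancement_mask)
        assert scaled.correction.value == pytest.approx(k * base.correction.value)
        assert scaled.threshold.value == pytest.approx(k * base.threshold.value, rel=1e-3)

    def test_threshold_fraction_monotonicity(self, rim_baseline):
        pre, post, truth, _ = rim_baseline
        v = {}
        for frac in (0.25, 0.40):
            v[frac] = quantify(
                pre, post, truth.tumor_narrow, truth.normal, truth.mucosa_roi,
                AnalysisParams(threshold_fraction=frac, skip_registration=True),
            ).volume_cm3
        assert v[0.40] <= v[0.25]

    def test_roi_subset_monotonicity(self, rim_baseline):
        pre, post, truth, _ = rim_baseline
        params = AnalysisParams(skip_registration=True)
        narrow = quantify(pre, post, truth.tumor_narrow, truth.normal, truth.mucosa_roi, params)
        generous = quantify(pre, post, truth.tumor_generous, truth.normal, truth.mucosa_roi, params)
        assert np.all(~truth.tumor_narrow.mask | truth.tumor_generous.mask)
        assert narrow.volume_cm3 <= generous.volume_cm3

    def test_stage_errors_name_their_stage(self, rim_baseline):
        from enhancevol.errors import PipelineStageError

        pre, post, truth, _ = rim_baseline
        bad_normal = RegionOfInterest(truth.tumor_narrow.mask.copy(), "normal", post.affine)
        with pytest.raises(PipelineStageError, match="validate-rois"):
            quantify(pre, post, truth.tumor_narrow, bad_normal, truth.mucosa_roi,
                     AnalysisParams(skip_registration=True))
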