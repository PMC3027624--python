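"""ROI rasterization, validation and transfer."""

import json

import numpy as np
import pytest

from enhancevol.errors import RoiError
from enhancevol.registration import RigidTransform
from enhancevol.rois import (
    PolygonSet,
    RegionOfInterest,
    check_disjoint,
    load_roi,
    rasterize,
    transfer_roi,
)
from enhancevol.volume_io import ImageVolume


def _point_in_polygon(x, y, verts):
    """Even-odd ray casting, independent of the shapely path used by rasterize."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


@pytest.fixture()
def grid():
    affine = np.eye(4)
    return ImageVolume(np.zeros((30, 30, 4)), (1.0, 1.0, 1.0), affine)


SQUARE = [[4.5, 4.5], [14.5, 4.5], [14.5, 14.5], [4.5, 14.5]]


class TestRasterize:
    def test_square_matches_brute_force(self, grid):
        roi = rasterize(PolygonSet("tumor", {1: [np.array(SQUARE)]}), grid)
        assert roi.voxel_count == 100
        oracle = np.zeros(grid.shape[:2], bool)
        for i in range(30):
            for j in range(30):
                oracle[i, j] = _point_in_polygon(float(i), float(j), SQUARE)
        assert np.array_equal(roi.mask[:, :, 1], oracle)
        assert not roi.mask[:, :, 0].any()

    def test_per_slice_additivity(self, grid):
        roi = rasterize(
            PolygonSet("tumor", {1: [np.array(SQUARE)], 2: [np.array(SQUARE)]}), grid
        )
        assert roi.voxel_count == 200

    def test_subvoxel_polygon_rasterizes_to_zero(self, grid):
        tiny = np.array([[5.2, 5.2], [5.4, 5.2], [5.3, 5.4]])  # between voxel centers
        with pytest.raises(RoiError, match="zero voxels"):
            rasterize(PolygonSet("tumor", {0: [tiny]}), grid)

    def test_vertex_ordering_irrelevant(self, grid):
        cw = rasterize(PolygonSet("tumor", {0: [np.array(SQUARE)]}), grid)
        ccw = rasterize(PolygonSet("tumor", {0: [np.array(SQUARE[::-1])]}), grid)
        assert np.array_equal(cw.mask, ccw.mask)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0.0, 0.0], [2.0, 2.0], [2.0, 0.0], [0.0, 2.0]])
        with pytest.raises(RoiError, match="self-intersecting"):
            PolygonSet("tumor", {0: [bowtie]})

    def test_json_round_trip(self, grid, tmp_path):
        ps = PolygonSet("normal", {1: [np.array(SQUARE)]})
        ps.to_json(tmp_path / "roi.json", reference_id="post")
        back = PolygonSet.from_json(tmp_path / "roi.json")
        assert back.role == "normal"
        assert np.array_equal(
            rasterize(back, grid).mask, rasterize(ps, grid).mask
        )


class TestTransfer:
    def test_identity_transfer_preserves_mask(self, rim_baseline):
        _, post, truth, _ = rim_baseline
        out = transfer_roi(truth.tumor_narrow, RigidTransform.identity(), post)
        assert np.array_equal(out.mask, truth.tumor_narrow.mask)
        assert out.source == "transferred"

    def test_integer_voxel_shift_matches_index_oracle(self, rim_baseline):
        _, post, truth, _ = rim_baseline
        dx = post.spacing[0]
        t = RigidTransform((0.0, 0.0, 0.0), (2 * dx, 0.0, 0.0))
        out = transfer_roi(truth.tumor_narrow, t, post)
        oracle = np.zeros_like(truth.tumor_narrow.mask)
        oracle[2:, :, :] = truth.tumor_narrow.mask[:-2, :, :]
        assert np.array_equal(out.mask, oracle)

    def test_round_trip_dice(self, rim_baseline):
        _, post, truth, _ = rim_baseline
        roi = truth.tumor_narrow
        assert roi.voxel_count >= 1000
        t = RigidTransform((0.0, 0.0, 3.0), (3.0, -2.0, 1.0))
        back = transfer_roi(transfer_roi(roi, t, post), t.inverse(), post)
        overlap = int(np.sum(back.mask & roi.mask))  # brute-force overlap count
        dice = 2.0 * overlap / (back.voxel_count + roi.voxel_count)
        assert dice >= 0.9

    def test_transfer_out_of_field_is_error(self, rim_baseline):
        _, post, truth, _ = rim_baseline
        t = RigidTransform((0.0, 0.0, 0.0), (500.0, 0.0, 0.0))
        with pytest.raises(RoiError, match="empty"):
            transfer_roi(truth.tumor_narrow, t, post)


class TestValidation:
    def test_overlapping_tumor_and_normal_rejected(self, grid):
        mask = np.zeros(grid.shape, bool)
        mask[5:10, 5:10, :] = True
        tumor = RegionOfInterest(mask, "tumor", grid.affine)
        normal = RegionOfInterest(mask.copy(), "normal", grid.affine)
        with pytest.raises(RoiError, match="overlap"):
            check_disjoint(tumor, normal)

    def test_empty_mask_rejected(self, grid):
        with pytest.raises(RoiError, match="empty"):
            RegionOfInterest(np.zeros(grid.shape, bool), "tumor", grid.affine)

    def test_subset_rois_give_subset_masks(self, grid):
        inner = PolygonSet("tumor", {0: [np.array([[6.5, 6.5], [12.5, 6.5], [12.5, 12.5], [6.5, 12.5]])]})
        outer = PolygonSet("tumor", {0: [np.array(SQUARE)]})
        mi, mo = rasterize(inner, grid).mask, rasterize(outer, grid).mask
        assert np.all(~mi | mo)  # inner mask is a strict subset
        assert mi.sum() < mo.sum()

    def test_load_roi_small_normal_rejected(self, grid, tmp_path):
        mask = np.zeros(grid.shape)
        mask[3, 3, 0] = 1.0
        vol = ImageVolume(mask, grid.spacing, grid.affine)
        from enhancevol.volume_io import write_volume

        write_volume(vol, tmp_path / "n.nii.gz")
        with pytest.raises(RoiError, match="normal"):
            load_roi(tmp_path / "n.nii.gz", "normal", grid)
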