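"""Overlapping block grid and the >= 4 components cluster rule."""

import numpy as np
import pytest

from mcdetect import detect_clusters, make_grid, merge_detections
from mcdetect.errors import ParameterError
from mcdetect.segment import Component, ComponentSet


def component_set(centroids, shape=(400, 400), spacing=0.05):
    comps = [
        Component(
            label=i + 1,
            pixel_count=1,
            centroid_px=(float(r), float(c)),
            bbox_px=(int(r), int(r) + 2, int(c), int(c) + 2),
            centroid_mm=(r * spacing, c * spacing),
        )
        for i, (r, c) in enumerate(centroids)
    ]
    return ComponentSet(comps, shape, 8, spacing)


class TestMakeGrid:
    def test_exact_tiling_400(self):
        grid = make_grid((400, 400), 200, 100)
        assert grid.row_anchors == [0, 100, 200]
        assert grid.n_blocks == 9

    def test_single_block_when_image_equals_block(self):
        grid = make_grid((200, 200), 200, 100)
        assert grid.n_blocks == 1
        assert grid.block_box(0, 0) == (0, 200, 0, 200)

    def test_last_anchor_clamped_to_image_edge(self):
        grid = make_grid((450, 450), 200, 100)
        assert grid.row_anchors == [0, 100, 200, 250]
        assert grid.n_blocks == 16

    def test_every_pixel_covered(self):
        for extent in [200, 250, 399, 450, 1000]:
            grid = make_grid((extent, extent), 200, 100)
            covered = np.zeros(extent, bool)
            for a in grid.row_anchors:
                covered[a : a + 200] = True
            assert covered.all()

    def test_block_larger_than_image_rejected(self):
        with pytest.raises(ParameterError):
            make_grid((150, 400), 200, 100)

    def test_step_larger_than_block_rejected(self):
        with pytest.raises(ParameterError):
            make_grid((400, 400), 100, 200)

    def test_default_block_spans_10mm_at_default_spacing(self):
        grid = make_grid((400, 400))
        assert grid.block_px * 0.05 == pytest.approx(10.0)


class TestDetectClusters:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_detection_iff_at_least_four_components(self, k):
        # k centroids packed inside the top-left block only
        comps = component_set([(10 + 3 * i, 10) for i in range(k)])
        grid = make_grid((400, 400), 200, 100)
        dets = detect_clusters(comps, grid, min_count=4)
        if k >= 4:
            assert dets, f"k={k} should be detected"
            assert all(d.component_count >= 4 for d in dets)
        else:
            assert dets == []

    def test_membership_is_by_centroid_half_open_box(self):
        # centroid on a block's far edge belongs to the next block
        comps = component_set([(200.0, 50.0)] * 4, shape=(400, 400))
        grid = make_grid((400, 400), 200, 100)
        dets = detect_clusters(comps, grid, 4)
        for d in dets:
            r0, r1, c0, c1 = d.bbox_px
            assert r0 <= 200.0 < r1

    def test_overlap_region_hits_multiple_blocks(self):
        # 4 components inside the interior 100x100 overlap region
        # [100,200)x[100,200) belong to 4 overlapping blocks
        comps = component_set([(110, 110), (120, 150), (150, 120), (190, 190)])
        grid = make_grid((400, 400), 200, 100)
        dets = detect_clusters(comps, grid, 4)
        assert len(dets) == 4
        merged = merge_detections(dets)
        assert len(merged) == 1
        assert merged[0].component_count == 4

    def test_member_centroids_inside_block_box(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 400, size=(40, 2))
        comps = component_set([tuple(p) for p in pts])
        grid = make_grid((400, 400), 200, 100)
        cents = {c.label: c.centroid_px for c in comps}
        for d in detect_clusters(comps, grid, 4):
            r0, r1, c0, c1 = d.bbox_px
            for lab in d.member_labels:
                r, c = cents[lab]
                assert r0 <= r < r1 and c0 <= c < c1

    def test_monotone_adding_component_never_removes_detection(self):
        base = [(10, 10), (20, 20), (30, 30), (40, 40)]
        grid = make_grid((400, 400), 200, 100)
        d_before = detect_clusters(component_set(base), grid, 4)
        d_after = detect_clusters(component_set(base + [(300, 300)]), grid, 4)
        blocks_before = {d.block_index for d in d_before}
        blocks_after = {d.block_index for d in d_after}
        assert blocks_before <= blocks_after

    def test_mm_box_uses_component_spacing(self):
        comps = component_set([(10, 10)] * 4, spacing=0.1)
        grid = make_grid((400, 400), 200, 100)
        det = detect_clusters(comps, grid, 4)[0]
        assert det.bbox_mm == pytest.approx((0.0, 20.0, 0.0, 20.0))

    def test_shape_mismatch_rejected(self):
        comps = component_set([(10, 10)], shape=(300, 300))
        grid = make_grid((400, 400), 200, 100)
        with pytest.raises(ParameterError):
            detect_clusters(comps, grid, 4)


class TestMergeDetections:
    def test_single_detection_unchanged(self):
        comps = component_set([(10, 10), (20, 20), (30, 30), (40, 40)])
        grid = make_grid((400, 400), 200, 100)
        dets = detect_clusters(comps, grid, 4)
        merged = merge_detections(dets)
        assert len(merged) >= 1

    def test_disjoint_member_sets_stay_separate(self):
        comps = component_set(
            [(10, 10), (15, 15), (20, 20), (25, 25),
             (310, 310), (315, 315), (320, 320), (325, 325)]
        )
        grid = make_grid((400, 400), 200, 100)
        merged = merge_detections(detect_clusters(comps, grid, 4))
        assert len(merged) == 2
        sets = [set(d.member_labels) for d in merged]
        assert sets[0].isdisjoint(sets[1])

    def test_idempotent(self):
        comps = component_set([(110, 110), (120, 150), (150, 120), (190, 190)])
        grid = make_grid((400, 400), 200, 100)
        merged = merge_detections(detect_clusters(comps, grid, 4))
        again = merge_detections(merged)
        assert [d.member_labels for d in again] == [d.member_labels for d in merged]
        assert [d.bbox_px for d in again] == [d.bbox_px for d in merged]

    def test_merged_bbox_is_union(self):
        comps = component_set([(110, 110), (120, 150), (150, 120), (190, 190)])
        grid = make_grid((400, 400), 200, 100)
        raw = detect_clusters(comps, grid, 4)
        merged = merge_detections(raw)[0]
        assert merged.bbox_px[0] == min(d.bbox_px[0] for d in raw)
        assert merged.bbox_px[1] == max(d.bbox_px[1] for d in raw)
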