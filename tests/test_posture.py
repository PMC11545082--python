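"""Dynamic-threshold segmentation and geometric filtering."""

import numpy as np
import pytest
from skimage.measure import label

from cagepose import (
    DetectionParams,
    KeyArea,
    SceneConfig,
    TroughLocation,
    compute_key_area,
    denoise_mask,
    detect_lying,
    extract_boxes,
    filter_columns,
    generate_scene,
    iou,
    locate_trough_variance,
    merge_contours,
    segment_key_area,
)


def _segment_oracle(depth, trough, key, k2, k3):
    """Literal per-pixel transcription of the foreground rule."""
    mask = np.zeros(depth.shape, dtype=bool)
    mid = (trough.row_top + trough.row_bottom) // 2
    for c in range(key.x, key.x + key.w):
        d_c = int(depth[mid, c])
        if d_c == 0:
            continue
        for r in range(key.y, key.y + key.h):
            d = int(depth[r, c])
            if d > 0 and d_c + k2 < d < d_c + k3:
                mask[r, c] = True
    return mask


class TestSegmentKeyArea:
    def _setup(self, depth_value=600):
        depth = np.zeros((48, 64), np.uint16)
        depth[8:16, :] = depth_value  # trough band
        trough = TroughLocation(8, 16, 4, 60)
        key = KeyArea(x=4, y=16, w=56, h=20)
        return depth, trough, key

    @pytest.mark.parametrize(
        "pixel_depth,expected",
        [
            (700, True),  # 665 < 700 < 850
            (660, False),  # 660 ≤ 665: strict lower bound
            (665, False),  # boundary exactly: excluded
            (850, False),  # boundary exactly: excluded
            (849, True),
        ],
    )
    def test_band_arithmetic(self, pixel_depth, expected):
        depth, trough, key = self._setup()
        depth[20, 10] = pixel_depth
        mask = segment_key_area(depth, trough, key, k2=65, k3=250)
        assert mask[20, 10] == expected

    def test_zero_reference_column_skipped(self):
        depth, trough, key = self._setup()
        depth[(trough.row_top + trough.row_bottom) // 2, 10] = 0
        depth[20, 10] = 700
        mask = segment_key_area(depth, trough, key, k2=65, k3=250)
        assert not mask[:, 10].any()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        depth = rng.integers(0, 1200, (48, 64)).astype(np.uint16)
        trough = TroughLocation(8, 16, 4, 60)
        key = KeyArea(x=4, y=16, w=56, h=24)
        fast = segment_key_area(depth, trough, key, k2=65, k3=250)
        np.testing.assert_array_equal(fast, _segment_oracle(depth, trough, key, 65, 250))

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_band_width(self, seed):
        # widening (k2, k3) can only grow the foreground set
        rng = np.random.default_rng(100 + seed)
        depth = rng.integers(0, 1200, (48, 64)).astype(np.uint16)
        trough = TroughLocation(8, 16, 4, 60)
        key = KeyArea(x=4, y=16, w=56, h=24)
        narrow = segment_key_area(depth, trough, key, k2=80, k3=200)
        wide = segment_key_area(depth, trough, key, k2=65, k3=250)
        assert (wide | narrow == wide).all()

    def test_recovers_generated_blob(self):
        cfg = SceneConfig(seed=7, roll_angle_deg=0.0, depth_noise_sd_mm=0.0,
                          dropout_fraction=0.0)
        frame, ann = generate_scene(cfg)
        trough = locate_trough_variance(frame.depth)
        key = compute_key_area(trough, (frame.width, frame.height))
        mask = segment_key_area(frame.depth, trough, key)
        region = np.s_[key.y : key.y + key.h, key.x : key.x + key.w]
        # blob pixels sit between the trough plane and the background
        blob = (frame.depth > 650) & (frame.depth < 870)
        covered = (mask & blob)[region].sum() / blob[region].sum()
        assert covered >= 0.90
        background = mask[region] & ~blob[region]
        assert background.sum() / background.size <= 0.02


class TestDenoise:
    def test_salt_noise_removed(self, rng):
        mask = np.zeros((60, 80), bool)
        pts = rng.integers(0, 60, (30, 2))
        mask[pts[:, 0], np.clip(pts[:, 1], 0, 79)] = True  # isolated specks
        assert not denoise_mask(mask).any()

    def test_large_rectangle_preserved(self):
        mask = np.zeros((80, 100), bool)
        mask[20:50, 25:75] = True  # 50×30 solid block
        out = denoise_mask(mask)
        assert out[21:49, 26:74].all()  # interior intact (≤1 px erosion)
        assert not out[:19, :].any() and not out[51:, :].any()

    def test_empty_mask_unchanged(self):
        assert not denoise_mask(np.zeros((40, 40), bool)).any()


class TestFilterColumns:
    def test_strict_threshold(self):
        mask = np.zeros((100, 3), bool)
        mask[:51, 0] = True  # N_c = 51 > 100/2 → kept
        mask[:50, 1] = True  # N_c = 50: strict inequality → erased
        out = filter_columns(mask, h_roi=100, k4=2.0)
        assert out[:, 0].sum() == 51
        assert out[:, 1].sum() == 0

    def test_all_white_unchanged(self):
        mask = np.ones((40, 20), bool)
        np.testing.assert_array_equal(filter_columns(mask, 40, 2.0), mask)

    def test_exact_boundary_erases_everything(self):
        mask = np.zeros((40, 20), bool)
        mask[:20, :] = True  # every column exactly at H/k4
        assert not filter_columns(mask, 40, 2.0).any()


class TestMergeContours:
    def _blob_pair(self, gap):
        mask = np.zeros((60, 120), bool)
        mask[20:40, 10:30] = True
        mask[20:40, 30 + gap : 50 + gap] = True
        return mask

    def test_close_blobs_fused(self):
        merged = merge_contours(self._blob_pair(gap=15), gap=20)
        assert label(merged, connectivity=2).max() == 1

    def test_distant_blobs_kept_apart(self):
        merged = merge_contours(self._blob_pair(gap=25), gap=20)
        assert label(merged, connectivity=2).max() == 2

    def test_contour_not_centroid_distance(self):
        # two long bars nearly touching: centroids are ~105 px apart, yet
        # the contours are 5 px apart, so they must fuse
        mask = np.zeros((60, 240), bool)
        mask[20:40, 10:110] = True
        mask[20:40, 115:215] = True
        merged = merge_contours(mask, gap=20)
        assert label(merged, connectivity=2).max() == 1

    def test_idempotent(self, rng):
        mask = rng.random((50, 80)) < 0.02
        mask |= np.roll(mask, 1, axis=1)  # make some 2-px blobs
        once = merge_contours(mask, gap=10)
        twice = merge_contours(once, gap=10)
        np.testing.assert_array_equal(once, twice)


class TestExtractBoxes:
    def _mask_with_rect(self, w, h):
        mask = np.zeros((200, 200), bool)
        mask[50 : 50 + h, 60 : 60 + w] = True
        return mask

    @pytest.mark.parametrize(
        "w,h,kept",
        [
            (80, 40, True),  # W/H = 2.0 > 1.7: flat-wide, lying bird
            (30, 90, False),  # pillar-like
            (85, 50, False),  # W/H = 1.7 exactly: strict inequality
        ],
    )
    def test_aspect_ratio_rule(self, w, h, kept):
        dets = extract_boxes(self._mask_with_rect(w, h), min_area=50, k5=1.7)
        assert (len(dets) == 1) == kept
        if kept:
            assert dets[0].box == (60, 50, w, h)

    def test_small_contours_dropped(self):
        dets = extract_boxes(self._mask_with_rect(7, 4), min_area=50, k5=1.7)
        assert dets == []

    def test_emitted_detections_satisfy_aspect_rule(self, rng):
        mask = rng.random((100, 200)) < 0.1
        for det in extract_boxes(mask, min_area=10, k5=1.7):
            assert det.w / det.h > 1.7


class TestDetectLying:
    def test_full_scene(self, default_scene):
        frame, ann = default_scene
        dets = detect_lying(frame)
        lying = ann.with_label("lying")
        assert len(dets) == len(lying) == 2
        for truth in lying:
            assert max(iou(d, truth) for d in dets) >= 0.5

    def test_standing_only_scene_yields_nothing(self):
        cfg = SceneConfig(seed=21, n_lying=0, n_standing=2, n_pillars=0)
        frame, ann = generate_scene(cfg)
        assert ann.with_label("lying") == []
        assert detect_lying(frame) == []

    def test_empty_scene_yields_nothing(self):
        cfg = SceneConfig(seed=22, n_lying=0, n_standing=0, n_pillars=0)
        frame, _ = generate_scene(cfg)
        assert detect_lying(frame) == []

    def test_pillars_rejected(self):
        cfg = SceneConfig(seed=23, n_lying=1, n_standing=0, n_pillars=2)
        frame, ann = generate_scene(cfg)
        dets = detect_lying(frame)
        assert len(dets) == 1
        for pillar in ann.with_label("pillar"):
            for det in dets:
                assert iou(det, pillar) < 0.3

    def test_unfindable_trough_returns_empty(self, rng):
        from cagepose import MergedFrame

        depth = rng.integers(1, 5000, (480, 640)).astype(np.uint16)
        frame = MergedFrame(np.zeros((480, 640, 3), np.uint8), depth)
        assert detect_lying(frame) == []
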