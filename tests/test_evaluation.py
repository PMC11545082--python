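"""IoU matching, metric identities, grid search, and the status rule."""

import itertools

import numpy as np
import pytest

from cagepose import (
    Box,
    ConfusionCounts,
    daily_status,
    evaluate_frames,
    grid_search,
    iou,
    match_and_count,
    metrics,
)


class TestIou:
    def test_identical_boxes(self):
        assert iou((3, 4, 10, 10), (3, 4, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 10, 10), (100, 100, 5, 5)) == 0.0

    def test_half_overlap(self):
        assert iou((0, 0, 10, 10), (5, 0, 10, 10)) == pytest.approx(1 / 3)

    def test_zero_area_box(self):
        assert iou((0, 0, 0, 10), (0, 0, 10, 10)) == 0.0


class TestMatching:
    def test_perfect_match(self):
        counts = match_and_count([(10, 10, 40, 20)], [Box(10, 10, 40, 20, "lying")], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)

    def test_spurious_detection(self):
        counts = match_and_count([(10, 10, 40, 20)], [], 0.5)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (0, 1, 0, 0)

    def test_missed_annotation(self):
        counts = match_and_count([], [Box(10, 10, 40, 20, "lying")], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 1)

    def test_empty_frame_counts_one_true_negative(self):
        counts = match_and_count([], [], 0.5)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (0, 0, 0, 1)

    def test_one_to_one_matching(self):
        # two detections on one annotation: greedy matching must agree
        # with brute-force optimal assignment on this instance
        dets = [(10, 10, 40, 20), (12, 10, 40, 20)]
        anns = [Box(10, 10, 40, 20, "lying")]
        counts = match_and_count(dets, anns, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)
        best_tp = max(
            sum(1 for d, a in zip(perm, anns) if iou(d, a) >= 0.5)
            for perm in itertools.permutations(dets, len(anns))
        )
        assert counts.tp == best_tp

    def test_threshold_one_requires_pixel_identity(self):
        dets = [(10, 10, 40, 20), (50, 50, 30, 15)]
        anns = [Box(10, 10, 40, 20, "lying"), Box(50, 51, 30, 15, "lying")]
        counts = match_and_count(dets, anns, 1.0)
        assert counts.tp == 1  # only the exact box matches

    def test_non_lying_labels_ignored(self):
        anns = [Box(10, 10, 10, 40, "pillar"), Box(70, 10, 20, 8, "standing")]
        counts = match_and_count([], anns, 0.5)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (0, 0, 0, 1)


class TestMetrics:
    def test_balanced_counts(self):
        s = metrics(ConfusionCounts(tp=8, tn=8, fp=2, fn=2))
        assert (s.accuracy, s.precision, s.recall, s.f1) == pytest.approx(
            (0.8, 0.8, 0.8, 0.8)
        )

    def test_degenerate_counts_warn(self):
        with pytest.warns(UserWarning, match="precision"):
            s = metrics(ConfusionCounts(tp=0, fp=0, fn=5))
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0)

    def test_harmonic_mean(self):
        s = metrics(ConfusionCounts(tp=1, fp=0, fn=1))  # P=1, R=0.5
        assert s.f1 == pytest.approx(2 / 3, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts())

    def test_f1_identity_two_forms(self, rng):
        # 2PR/(P+R) must equal 2TP/(2TP+FP+FN)
        for _ in range(200):
            tp, fp, fn = (int(v) for v in rng.integers(0, 50, 3))
            if tp + fp + fn == 0:
                continue
            s = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=1))
            alt = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            assert abs(s.f1 - alt) < 1e-12

    def test_f1_non_increasing_in_iou_threshold(self, rng):
        dets, anns = [], []
        for _ in range(30):
            x, y = rng.integers(0, 500, 2)
            w, h = rng.integers(10, 60, 2)
            anns.append(Box(int(x), int(y), int(w), int(h), "lying"))
            jx, jy = rng.integers(-8, 9, 2)
            dets.append((int(x + jx), int(y + jy), int(w), int(h)))
        f1s = []
        for thr in np.arange(0.3, 1.0, 0.1):
            s = metrics(match_and_count(dets, anns, thr) + ConfusionCounts(tn=1))
            f1s.append(s.f1)
        assert all(a >= b - 1e-12 for a, b in zip(f1s, f1s[1:]))


@pytest.fixture(scope="module")
def small_dataset():
    from cagepose import SceneConfig, generate_frames

    return list(generate_frames(4, SceneConfig(seed=6, roll_angle_deg=0.5)))


class TestGridSearch:
    def test_single_point_grid(self, small_dataset):
        best, table = grid_search(small_dataset, {"k2": [65.0]})
        assert best.k2 == 65.0
        assert len(table) == 1

    def test_argmax_returned(self, small_dataset):
        grid = {"k2": [65.0, 230.0]}  # 230 excludes most body pixels
        best, table = grid_search(small_dataset, grid)
        assert best.k2 == table.loc[table["f1"].idxmax(), "k2"]
        assert best.k2 == 65.0

    def test_recovers_offset_band(self, small_dataset):
        # lying offsets are drawn around 150 mm: the F1-optimal band
        # must bracket 150
        grid = {"k2": [35.0, 65.0, 175.0], "k3": [130.0, 250.0]}
        best, table = grid_search(small_dataset, grid)
        assert best.k2 < 150 < best.k3
        assert len(table) == 5  # the k2=175, k3=130 corner is infeasible

    def test_empty_grid_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            grid_search(small_dataset, {})


class TestDailyStatus:
    @pytest.mark.parametrize(
        "lying,total,expected",
        [
            (6, 10, "abnormal"),
            (0, 10, "normal"),
            (5, 10, "abnormal"),  # the 50% boundary flags abnormal
            (4, 10, "normal"),
        ],
    )
    def test_threshold_rule(self, lying, total, expected):
        obs = [(t, t < lying) for t in range(total)]
        report = daily_status(obs, bird_id="cage-7")
        assert report.status == expected
        assert report.lying_fraction == pytest.approx(lying / total)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            daily_status([])
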