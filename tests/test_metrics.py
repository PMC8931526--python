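import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siamtrack import (
    BBox,
    CorrectionLog,
    Source,
    Trajectory,
    TrajectoryRecord,
    box_size_sweep,
    evaluate,
    overlap_rate,
    pixel_error,
)

from conftest import rasterized_iou

int_boxes = st.builds(
    BBox,
    st.integers(0, 20).map(float),
    st.integers(0, 20).map(float),
    st.integers(1, 20).map(float),
    st.integers(1, 20).map(float),
)


class TestOverlapRate:
    def test_identical_and_disjoint(self):
        a = BBox(0, 0, 4, 4)
        assert overlap_rate(a, a) == 1.0
        assert overlap_rate(a, BBox(10, 10, 4, 4)) == 0.0

    def test_edge_sharing_boxes_have_zero_overlap(self):
        assert overlap_rate(BBox(0, 0, 4, 4), BBox(4, 0, 4, 4)) == 0.0

    def test_known_third_overlap(self):
        assert overlap_rate(BBox(0, 0, 4, 4), BBox(2, 0, 4, 4)) == pytest.approx(1 / 3)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(int_boxes, int_boxes)
    def test_matches_rasterized_pixel_count_oracle(self, a, b):
        assert overlap_rate(a, b) == pytest.approx(rasterized_iou(a, b), abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(int_boxes, int_boxes, st.integers(-30, 30), st.integers(-30, 30))
    def test_symmetry_and_translation_invariance(self, a, b, dx, dy):
        assert overlap_rate(a, b) == pytest.approx(overlap_rate(b, a), abs=1e-12)
        assert overlap_rate(a.translated(dx, dy), b.translated(dx, dy)) == pytest.approx(
            overlap_rate(a, b), abs=1e-12
        )


class TestPixelError:
    def test_three_four_five(self):
        assert pixel_error((0, 0), (3, 4)) == 5.0
        assert pixel_error((1, 1), (1, 1)) == 0.0

    def test_boxes_reduce_to_centers(self):
        assert pixel_error(BBox(0, 0, 2, 2), BBox(3, 4, 2, 2)) == 5.0

    def test_matches_sqrt_sum_oracle(self, rng):
        for _ in range(100):
            p, q = rng.standard_normal(2), rng.standard_normal(2)
            expected = float(np.sqrt(((p - q) ** 2).sum()))
            assert pixel_error(tuple(p), tuple(q)) == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pixel_error((np.nan, 0), (0, 0))


def _traj(boxes, sources=None):
    sources = sources or [Source.CORRECTED] + [Source.AUTO] * (len(boxes) - 1)
    return Trajectory(
        records=[
            TrajectoryRecord(i, b, 1.0, s) for i, (b, s) in enumerate(zip(boxes, sources))
        ]
    )


class TestEvaluate:
    def test_or_series_thresholding(self):
        # OR values engineered as 1.0, 1/3, 1.0 against truth
        boxes = [BBox(0, 0, 4, 4), BBox(2, 10, 4, 4), BBox(20, 20, 4, 4)]
        truth = {0: BBox(0, 0, 4, 4), 1: BBox(0, 10, 4, 4), 2: BBox(20, 20, 4, 4)}
        rep = evaluate(_traj(boxes), truth)
        assert rep.success_rate == pytest.approx(2 / 3)
        assert rep.error_rate == pytest.approx(1 / 3)
        assert rep.success_rate + rep.error_rate == 1.0

    def test_or_threshold_inclusive_pe_threshold_strict(self):
        # exactly 50% overlap counts as success; PE exactly 20 does not
        boxes = [BBox(0, 0, 4, 8)]
        truth = {0: BBox(0, 0, 4, 4)}
        rep = evaluate(_traj(boxes), truth, or_threshold=0.5)
        assert rep.or_series[0] == pytest.approx(0.5)
        assert rep.success_rate == 1.0
        boxes = [BBox(20, 0, 4, 4)]
        truth = {0: BBox(0, 0, 4, 4)}
        rep = evaluate(_traj(boxes), truth, pe_threshold=20.0)
        assert rep.pe_series[0] == pytest.approx(20.0)
        assert rep.accuracy == 0.0

    def test_perfect_trajectory(self):
        boxes = [BBox(i, i, 5, 5) for i in range(4)]
        truth = {i: BBox(i, i, 5, 5) for i in range(4)}
        rep = evaluate(_traj(boxes), truth)
        assert (rep.success_rate, rep.accuracy, rep.error_rate) == (1.0, 1.0, 0.0)

    def test_frames_missing_from_truth_counted(self):
        boxes = [BBox(0, 0, 5, 5), BBox(1, 1, 5, 5)]
        truth = {0: BBox(0, 0, 5, 5)}
        rep = evaluate(_traj(boxes), truth)
        assert rep.n_frames == 1 and rep.n_missing_truth == 1

    def test_no_overlapping_frames_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_traj([BBox(0, 0, 5, 5)]), {99: BBox(0, 0, 5, 5)})

    def test_label_effort_included(self):
        from siamtrack import CorrectionEvent

        log = CorrectionLog(
            events=[CorrectionEvent(5, BBox(0, 0, 2, 2))], total_frames=200
        )
        boxes = [BBox(0, 0, 5, 5)]
        rep = evaluate(_traj(boxes), {0: BBox(0, 0, 5, 5)}, log=log)
        assert rep.label_effort_percent == pytest.approx(0.5)

    def test_success_monotone_in_or_threshold(self, rng):
        boxes, truth = [], {}
        for i in range(30):
            off = float(rng.random() * 5)
            boxes.append(BBox(off, 0, 5, 5))
            truth[i] = BBox(0, 0, 5, 5)
        traj = _traj(boxes)
        rates = [evaluate(traj, truth, or_threshold=t).success_rate for t in (0.2, 0.5, 0.8)]
        assert rates[0] >= rates[1] >= rates[2]
        accs = [evaluate(traj, truth, pe_threshold=t).accuracy for t in (1.0, 3.0, 6.0)]
        assert accs[0] <= accs[1] <= accs[2]


class TestBoxSizeSweep:
    def test_inflation_changes_success(self):
        boxes = [BBox(0, 0, 4, 4)]
        truth = {0: BBox(1, 1, 2, 2)}  # concentric, quarter-area: IoU 0.25
        sweep = box_size_sweep(_traj(boxes), truth, factors=(1.0, 2.0))
        assert sweep[1.0] == 0.0
        assert sweep[2.0] == 1.0  # doubled truth coincides with the box
        with pytest.raises(ValueError):
            box_size_sweep(_traj(boxes), truth, factors=(0.0,))
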