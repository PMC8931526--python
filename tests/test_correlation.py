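import numpy as np
import pytest

from siamtrack import BBox, compute_confidence, cross_correlate, locate_peak, suppress_distractors
from siamtrack.features import FeatureMap
from siamtrack.tracker import CandidateSpec, ResponseMap, select_box_candidate, window_energy

from conftest import brute_force_correlate


def fmap(grid, stride=1.0, origin=(0.5, 0.5)):
    return FeatureMap(grid=np.asarray(grid, dtype=float), stride=stride, origin=origin)


def resp(scores, stride=1.0, origin=(0.0, 0.0)):
    return ResponseMap(scores=np.asarray(scores, dtype=float), stride=stride, origin=origin)


class TestCrossCorrelate:
    def test_unit_template_reproduces_search(self):
        out = cross_correlate(fmap([[[1.0]]]), fmap([[[1.0, 2.0], [3.0, 4.0]]]))
        np.testing.assert_allclose(out.scores, [[1, 2], [3, 4]])

    def test_normalized_subwindow_peaks_at_its_offset(self, rng):
        search = rng.random((1, 12, 12))
        win = search[:, 3:8, 6:11].copy()
        # unit-normalize both per window so the matched offset wins globally
        t = win / np.linalg.norm(win)
        scores = cross_correlate(fmap(t), fmap(search)).scores
        energy = window_energy(fmap(search), 5, 5)
        ncc = scores / np.sqrt(energy)
        assert np.unravel_index(np.argmax(ncc), ncc.shape) == (3, 6)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(100):
            th, tw = rng.integers(1, 6, 2)
            sh, sw = th + rng.integers(0, 10), tw + rng.integers(0, 10)
            c = int(rng.integers(1, 4))
            t = rng.standard_normal((c, th, tw))
            s = rng.standard_normal((c, sh, sw))
            out = cross_correlate(fmap(t), fmap(s)).scores
            np.testing.assert_allclose(out, brute_force_correlate(t, s), atol=1e-6)

    def test_shape_and_channel_errors(self, rng):
        with pytest.raises(ValueError, match="channel"):
            cross_correlate(fmap(rng.random((2, 3, 3))), fmap(rng.random((3, 5, 5))))
        with pytest.raises(ValueError, match="larger"):
            cross_correlate(fmap(rng.random((1, 6, 6))), fmap(rng.random((1, 5, 5))))

    def test_response_origin_maps_to_window_centers(self):
        search = fmap(np.zeros((1, 5, 5)), stride=2.0, origin=(10.0, 20.0))
        out = cross_correlate(fmap(np.zeros((1, 3, 3))), search)
        # cell (0,0) scores the window whose centre is search cell (1,1)
        assert out.cell_center(0, 0) == (12.0, 22.0)


class TestSuppressDistractors:
    def test_alpha_zero_is_bitwise_identity(self, rng):
        r = resp(rng.random((4, 4)))
        s = fmap(rng.random((2, 6, 6)))
        d = [fmap(rng.random((2, 3, 3)))]
        out = suppress_distractors(r, s, d, alpha=0.0)
        assert out.scores is r.scores

    def test_self_distractor_scales_by_one_minus_alpha(self, rng):
        t = fmap(rng.random((2, 3, 3)))
        s = fmap(rng.random((2, 7, 7)))
        r = cross_correlate(t, s)
        out = suppress_distractors(r, s, [t], alpha=0.4)
        np.testing.assert_allclose(out.scores, 0.6 * r.scores, atol=1e-12)

    def test_two_blob_scene_suppresses_distractor_side_more(self):
        # search with two identical blobs; the distractor patch is the second
        # blob *with its surroundings*, so its correlation is anchored there
        s = np.zeros((1, 9, 16))
        blob = np.array([[0.2, 0.5, 0.2], [0.5, 1.0, 0.5], [0.2, 0.5, 0.2]])
        s[0, 3:6, 2:5] = blob
        s[0, 3:6, 10:13] = blob
        t = fmap(blob[None] / np.linalg.norm(blob))
        search = fmap(s)
        r = cross_correlate(t, search)
        # distractor feature: 3x3 window centred on the second blob
        d = fmap(s[:, 3:6, 10:13] / np.linalg.norm(s[:, 3:6, 10:13]))
        out = suppress_distractors(r, search, [d], alpha=0.5)
        drop_first = r.scores[3, 2] - out.scores[3, 2]
        drop_second = r.scores[3, 10] - out.scores[3, 10]
        assert drop_second > 0
        assert drop_second >= drop_first

    def test_mean_over_multiple_distractors(self, rng):
        s = fmap(rng.random((1, 8, 8)))
        t = fmap(rng.random((1, 3, 3)))
        r = cross_correlate(t, s)
        d1, d2 = fmap(rng.random((1, 3, 3))), fmap(rng.random((1, 3, 3)))
        out = suppress_distractors(r, s, [d1, d2], alpha=1.0)
        expected = r.scores - 0.5 * (
            cross_correlate(d1, s).scores + cross_correlate(d2, s).scores
        )
        np.testing.assert_allclose(out.scores, expected, atol=1e-12)


class TestLocatePeak:
    def test_single_maximum_no_window(self):
        s = np.zeros((5, 7))
        s[3, 2] = 1.0
        peak, _, raw = locate_peak(resp(s), (0.0, 0.0), window_weight=0.0)
        assert peak == (3, 2) and raw == 1.0

    def test_tie_breaks_row_major(self):
        s = np.zeros((6, 8))
        s[2, 5] = s[4, 1] = 1.0
        peak, _, _ = locate_peak(resp(s), (0.0, 0.0), window_weight=0.0)
        assert peak == (2, 5)

    def test_all_equal_map_degenerates_to_center(self):
        peak, _, _ = locate_peak(resp(np.ones((5, 9))), (0.0, 0.0), window_weight=0.0)
        assert peak == (2, 4)

    def test_strong_window_prefers_near_peak(self):
        s = np.zeros((11, 11))
        s[0, 10] = 1.0  # global max far away
        s[5, 5] = 0.9  # slightly smaller at the previous position
        r = resp(s, stride=1.0, origin=(0.0, 0.0))
        far, _, _ = locate_peak(r, (5.0, 5.0), window_weight=0.0)
        near, _, _ = locate_peak(r, (5.0, 5.0), window_weight=0.9)
        assert far == (0, 10)
        assert near == (5, 5)


class TestSelectBoxCandidate:
    def _responses(self, peak_scores, rows=7, cols=7):
        out = []
        for cand, sc in peak_scores:
            s = np.zeros((rows, cols))
            s[rows // 2, cols // 2] = sc
            out.append((cand, resp(s, stride=1.0, origin=(10.0, 10.0))))
        return out

    def test_size_damping_zero_keeps_previous_size(self):
        cands = [(CandidateSpec(1.0, 1.0), 1.0), (CandidateSpec(2.0, 1.04), 2.0)]
        box, _ = select_box_candidate(
            self._responses(cands), BBox(10, 10, 6, 6), size_damping=0.0
        )
        assert (box.w, box.h) == (6.0, 6.0)

    def test_tie_broken_by_candidate_order_identity_first(self):
        cands = [
            (CandidateSpec(1.0, 1.0), 1.0),
            (CandidateSpec(0.5, 1.0), 1.0),
            (CandidateSpec(2.0, 1.0), 1.0),
        ]
        _, winner = select_box_candidate(
            self._responses(cands), BBox(10, 10, 6, 6), size_damping=0.3
        )
        assert winner == "r=1,s=1"

    def test_winner_drives_center_and_damped_size(self):
        cands = [(CandidateSpec(1.0, 1.0), 0.5), (CandidateSpec(1.0, 1.04), 1.0)]
        box, winner = select_box_candidate(
            self._responses(cands), BBox(7, 7, 6, 6), size_damping=1.0
        )
        assert winner == "r=1,s=1.04"
        assert box.center == (13.0, 13.0)
        assert box.w == pytest.approx(6 * 1.04)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_box_candidate([], BBox(0, 0, 5, 5), 0.3)

    def test_center_clamped_inside_frame(self):
        cands = [(CandidateSpec(1.0, 1.0), 1.0)]
        responses = self._responses(cands)
        box, _ = select_box_candidate(
            responses, BBox(10, 10, 6, 6), 0.3, frame_size=(12, 12)
        )
        cx, cy = box.center
        assert 0 < cx < 12 and 0 < cy < 12


class TestComputeConfidence:
    def test_constant_5x5_map_is_nine_twentyfifths(self):
        assert compute_confidence(resp(np.ones((5, 5))), 0.1) == pytest.approx(9 / 25)

    def test_constant_small_map_is_min9_n_over_n(self):
        assert compute_confidence(resp(np.ones((2, 2))), 0.1) == pytest.approx(1.0)
        assert compute_confidence(resp(np.ones((1, 3))), 0.1) == pytest.approx(1.0)

    def test_dominant_peak_approaches_one(self):
        s = np.zeros((9, 9))
        s[4, 4] = 5.0  # gap of 5 against temperature 0.1
        assert compute_confidence(resp(s), 0.1) > 0.999

    def test_matches_softmax_oracle_on_random_maps(self, rng):
        for _ in range(100):
            s = rng.standard_normal((17, 17))
            got = compute_confidence(resp(s), 0.1)
            p = np.exp(s / 0.1 - np.max(s / 0.1))
            p /= p.sum()
            r, c = np.unravel_index(np.argmax(s), s.shape)
            expected = p[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2].sum()
            assert got == pytest.approx(expected, abs=1e-9)

    def test_bounds_and_errors(self, rng):
        s = rng.standard_normal((6, 6))
        v = compute_confidence(resp(s), 0.1)
        assert 0.0 < v <= 1.0
        with pytest.raises(ValueError):
            compute_confidence(resp(s), 0.0)
        with pytest.raises(ValueError):
            resp(np.array([[np.inf, 0.0]]))
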