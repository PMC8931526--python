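import numpy as np
import pytest

from siamtrack import (
    BBox,
    DetectionConfig,
    ExemplarBank,
    ExemplarDetector,
    FrameImage,
    Source,
    Trajectory,
    TrajectoryRecord,
    evaluate,
    fixture,
    gated_step,
    generate_scene,
    harvest_exemplars,
    load_bank,
    save_bank,
    track_sequence,
)
from siamtrack.tracker import TrackerConfig, init_state


@pytest.fixture(scope="module")
def dash_setup():
    """Dash scene plus a bank harvested from the easy prefix before the jump."""
    cfg = TrackerConfig()
    frames, truth, _ = generate_scene(fixture("dash"))
    prefix = frames[:60]
    traj = track_sequence(prefix, truth[0], cfg)
    bank = ExemplarBank()
    harvest_exemplars(traj, prefix, bank, cfg, seed=1)
    return cfg, frames, truth, traj, bank


def _traj_with_confidences(confs, boxes=None, sources=None):
    boxes = boxes or [BBox(10, 10, 20, 20)] * len(confs)
    sources = sources or [Source.CORRECTED] + [Source.AUTO] * (len(confs) - 1)
    return Trajectory(
        records=[
            TrajectoryRecord(i, b, c, s)
            for i, (b, c, s) in enumerate(zip(boxes, confs, sources))
        ]
    )


class TestHarvest:
    def test_low_confidence_records_not_harvested(self, dash_setup):
        cfg, frames, *_ = dash_setup
        traj = _traj_with_confidences([1.0, 0.5, 0.59, 0.2])
        bank = ExemplarBank()
        harvest_exemplars(traj, frames[:4], bank, cfg)
        assert len(bank) == 0

    def test_qualifying_records_counted_exactly(self, dash_setup):
        cfg, frames, *_ = dash_setup
        traj = _traj_with_confidences([1.0] + [0.9] * 10)
        bank = ExemplarBank()
        harvest_exemplars(traj, frames[:11], bank, cfg)
        assert len(bank) == 10  # record 0 is 'corrected', not harvested

    def test_reservoir_caps_reproducibly(self, dash_setup):
        cfg, frames, *_ = dash_setup
        # 59 qualifying records, capacity 20
        traj = _traj_with_confidences([1.0] + [0.9] * 59)
        b1, b2 = ExemplarBank(max_size=20), ExemplarBank(max_size=20)
        harvest_exemplars(traj, frames[:60], b1, cfg, seed=7)
        harvest_exemplars(traj, frames[:60], b2, cfg, seed=7)
        assert len(b1) == 20 and b1.n_seen == 59
        for (fa, sa), (fb, sb) in zip(b1.exemplars, b2.exemplars):
            assert np.array_equal(fa.grid, fb.grid) and sa == sb

    def test_harvest_purity_only_auto_sources(self, dash_setup):
        cfg, frames, *_ = dash_setup
        sources = [Source.CORRECTED, Source.DETECTED, Source.AUTO]
        traj = _traj_with_confidences([1.0, 0.95, 0.95], sources=sources)
        bank = ExemplarBank()
        harvest_exemplars(traj, frames[:3], bank, cfg)
        assert len(bank) == 1


class TestDetect:
    def test_empty_bank_rejected(self, dash_setup):
        cfg, frames, *_ = dash_setup
        det = ExemplarDetector(ExemplarBank(), DetectionConfig(), cfg)
        with pytest.raises(ValueError, match="empty"):
            det.detect(frames[0])

    def test_planted_target_found_within_stride(self, dash_setup):
        cfg, frames, truth, _, bank = dash_setup
        det = ExemplarDetector(bank, DetectionConfig(), cfg)
        found = det.detect(frames[71])  # just after the jump
        assert found is not None
        box, score = found
        (cx, cy), (tx, ty) = box.center, truth[71].center
        assert abs(cx - tx) <= det.cfg.scan_stride
        assert abs(cy - ty) <= det.cfg.scan_stride
        assert score >= det.cfg.accept_score_fraction

    def test_pure_noise_frame_yields_no_detection(self, dash_setup, rng):
        cfg, frames, _, _, bank = dash_setup
        det = ExemplarDetector(bank, DetectionConfig(), cfg)
        noise = FrameImage(pixels=rng.random(frames[0].pixels.shape), index=0)
        assert det.detect(noise) is None

    def test_self_match_on_source_frame(self, dash_setup):
        cfg, frames, truth, traj, _ = dash_setup
        # a bank of one exemplar, probed on the very frame and box it came from
        rec = next(r for r in traj.records if r.source is Source.AUTO and r.confidence >= 0.6)
        src = FrameImage(pixels=frames[rec.frame_index].pixels, index=1)
        bank = ExemplarBank()
        one = _traj_with_confidences([1.0, rec.confidence], boxes=[rec.box, rec.box])
        harvest_exemplars(one, [frames[0], src], bank, cfg)
        assert len(bank) == 1
        # score the window at exactly the exemplar's own centre
        det = ExemplarDetector(bank, DetectionConfig(), cfg)
        mat = det._exemplar_matrix()
        w, h = bank.median_box_size
        cx, cy = rec.box.center
        score = det._window_score(src, cx, cy, w, h, mat)
        assert score == pytest.approx(det.self_match_score, abs=1e-6)


class TestGating:
    def test_confident_step_never_invokes_detector(self, dash_setup):
        cfg, frames, truth, _, bank = dash_setup
        det = ExemplarDetector(bank, DetectionConfig(), cfg)
        state = init_state(frames[0], truth[0], cfg)
        for fr in frames[1:20]:  # easy prefix: confidence stays high
            state, rec = gated_step(state, fr, cfg, det)
            assert rec.confidence >= det.cfg.activation_threshold
        assert det.invocations == 0

    def test_low_confidence_invokes_and_rescues(self, dash_setup):
        cfg, frames, truth, _, bank = dash_setup
        det = ExemplarDetector(bank, DetectionConfig(), cfg)
        traj = track_sequence(frames, truth[0], cfg, detector=det)
        low = sum(
            1 for r in traj.records[1:] if r.confidence < det.cfg.activation_threshold
            and r.source is Source.AUTO
        )
        detected = [r for r in traj.records if r.source is Source.DETECTED]
        assert det.invocations >= 1
        assert len(detected) >= 1
        # every invocation came from a sub-threshold step
        assert det.invocations == low + len(detected)

    def test_empty_bank_is_advisory_no_failure(self, dash_setup):
        cfg, frames, truth, *_ = dash_setup
        state = init_state(frames[0], truth[0], cfg)
        det = ExemplarDetector(ExemplarBank(), DetectionConfig(), cfg)
        state, rec = gated_step(state, frames[75], cfg, det)  # far-off frame
        assert rec.source is Source.AUTO
        assert det.invocations == 0


class TestBankPersistence:
    def test_roundtrip(self, dash_setup, tmp_path):
        *_, bank = dash_setup
        path = tmp_path / "bank.npz"
        save_bank(bank, path)
        back = load_bank(path)
        assert len(back) == len(bank) and back.n_seen == bank.n_seen
        for (fa, sa), (fb, sb) in zip(bank.exemplars, back.exemplars):
            assert np.array_equal(fa.grid, fb.grid) and sa == sb

    def test_empty_bank_refused(self, tmp_path):
        with pytest.raises(ValueError):
            save_bank(ExemplarBank(), tmp_path / "b.npz")
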