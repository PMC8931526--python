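"""Human-in-the-loop correction: template replacement and label-effort bookkeeping.

A correction re-annotates the current frame with a fresh box; the tracker's
template is rebuilt from that box, the distractor memory is cleared and
tracking resumes from the corrected position.  The first-frame annotation
defines the target and is *not* counted as label effort; only corrections
made during tracking are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .tracker import TrackerConfig, TrackState, init_state, track_step
from .types import BBox, CorrectionEvent, FrameImage, Source, Trajectory, TrajectoryRecord


@dataclass
class CorrectionLog:
    """Corrections applied during a run, for label-effort accounting."""

    events: list[CorrectionEvent] = field(default_factory=list)
    total_frames: int = 0

    def __post_init__(self) -> None:
        idx = [e.frame_index for e in self.events]
        if idx != sorted(idx):
            raise ValueError("correction events must be sorted by frame index")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate correction events for one frame")


def apply_correction(
    state: TrackState, frame: FrameImage, box: BBox, cfg: TrackerConfig
) -> TrackState:
    """Replace the template with a new annotation of the current frame.

    The template feature is recomputed from ``(frame, box)``, the current
    box is moved to ``box``, the distractor memory is cleared and the
    confidence resets to 1.0.
    """
    if not (0 <= box.x and box.x2 <= frame.width and 0 <= box.y and box.y2 <= frame.height):
        raise ValueError(f"correction box {box} lies outside the {frame.width}x{frame.height} frame")
    return init_state(frame, box, cfg)


def label_effort(log: CorrectionLog) -> float:
    """Percent of frames that needed a human correction.

    ``100 * n_corrections / total_frames``; the initial annotation is
    excluded by construction (it never enters the log).
    """
    if log.total_frames < 1:
        raise ValueError("total_frames must be at least 1")
    return 100.0 * len(log.events) / log.total_frames


def track_with_oracle(
    frames: Sequence[FrameImage],
    initial_box: BBox,
    truth: dict[int, BBox],
    cfg: TrackerConfig | None = None,
    or_threshold: float = 0.5,
    overlap_fn: Callable[[BBox, BBox], float] | None = None,
) -> tuple[Trajectory, CorrectionLog]:
    """Track with an automatic ground-truth corrector standing in for the human.

    Whenever a tracked frame's overlap with ground truth drops below
    ``or_threshold``, the frame is corrected with the ground-truth box
    (template replaced, tracking resumes), exactly as an attentive operator
    would.  Returns the corrected trajectory and the correction log, from
    which the label-effort curve is computed.
    """
    from .metrics import overlap_rate

    ov = overlap_fn or overlap_rate
    cfg = cfg or TrackerConfig()
    state = init_state(frames[0], initial_box, cfg)
    records = [
        TrajectoryRecord(
            frame_index=frames[0].index, box=initial_box, confidence=1.0, source=Source.CORRECTED
        )
    ]
    events: list[CorrectionEvent] = []
    for frame in frames[1:]:
        state, record = track_step(state, frame, cfg)
        gt = truth.get(frame.index)
        if gt is not None and ov(record.box, gt) < or_threshold:
            state = apply_correction(state, frame, gt, cfg)
            events.append(CorrectionEvent(frame_index=frame.index, box=gt))
            record = TrajectoryRecord(
                frame_index=frame.index, box=gt, confidence=1.0, source=Source.CORRECTED
            )
        records.append(record)
    traj = Trajectory(records=records)
    traj.validate()
    return traj, CorrectionLog(events=events, total_frames=len(frames))
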