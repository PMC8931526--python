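"""Tracking-with-detection: a self-trained, confidence-gated fallback.

Confident automatic tracker outputs are harvested as exemplar features;
when the tracker's own confidence drops below the activation threshold
(0.3 by default) the exemplar detector scans the whole frame for the
target and, on success, re-seeds the tracker's position.  The detector is
advisory: if it finds nothing, the tracker's own output stands.  It never
replaces the template — only a human correction does that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FeatureMap, crop_and_resize, extract_features, pool_feature_map
from .tracker import TrackerConfig, TrackState, make_template, track_step
from .types import BBox, FrameImage, Source, Trajectory, TrajectoryRecord


@dataclass
class DetectionConfig:
    activation_threshold: float = 0.3
    accept_score_fraction: float = 0.7
    scan_stride: int = 8
    refine_radius: int = 8  # px; stride-1 local refinement around the best window
    # block-averaging factor for detection features: coarser cells widen the
    # match basin so the scan lattice cannot step over the target
    feature_downsample: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.activation_threshold <= 1.0):
            raise ValueError("activation_threshold must lie in [0, 1]")
        if self.scan_stride < 1:
            raise ValueError("scan_stride must be at least 1")


@dataclass
class ExemplarBank:
    """Reservoir of confident tracker outputs used as detection exemplars."""

    exemplars: list[tuple[FeatureMap, tuple[float, float]]] = field(default_factory=list)
    max_size: int = 50
    min_harvest_confidence: float = 0.6
    n_seen: int = 0  # qualifying records seen so far (drives the reservoir)

    def __len__(self) -> int:
        return len(self.exemplars)

    @property
    def median_box_size(self) -> tuple[float, float]:
        if not self.exemplars:
            raise ValueError("empty exemplar bank")
        ws = sorted(s[0] for _, s in self.exemplars)
        hs = sorted(s[1] for _, s in self.exemplars)
        return (float(np.median(ws)), float(np.median(hs)))


def harvest_exemplars(
    traj: Trajectory,
    frames: Sequence[FrameImage],
    bank: ExemplarBank,
    cfg: TrackerConfig | None = None,
    seed: int = 0,
) -> ExemplarBank:
    """Add confident automatic records to the bank (mutates and returns it).

    Only records with ``source == auto`` and confidence at or above the
    harvest threshold qualify; their template-style feature is extracted
    from the record's box.  When the bank overflows, seeded reservoir
    sampling keeps a uniform subsample of everything seen so far.
    """
    cfg = cfg or TrackerConfig()
    rng = np.random.default_rng(seed)
    by_index = {f.index: f for f in frames}
    for rec in traj.records:
        if rec.source is not Source.AUTO or rec.confidence < bank.min_harvest_confidence:
            continue
        frame = by_index.get(rec.frame_index)
        if frame is None:
            continue
        feat, _, _ = make_template(frame, rec.box, cfg)
        item = (feat, (rec.box.w, rec.box.h))
        if len(bank.exemplars) < bank.max_size:
            bank.exemplars.append(item)
        else:
            j = int(rng.integers(0, bank.n_seen + 1))
            if j < bank.max_size:
                bank.exemplars[j] = item
        bank.n_seen += 1
    return bank


class ExemplarDetector:
    """Whole-frame scanning detector built from the exemplar bank.

    Each scan window is cropped, featured and normalized exactly like a
    template; its score is the best cosine similarity against any
    exemplar.  A detection is accepted when the best window reaches
    ``accept_score_fraction`` of the bank's self-match score (1.0 for
    unit-norm exemplars).  A stride-1 local refinement sharpens the coarse
    scan-grid localisation.
    """

    def __init__(
        self,
        bank: ExemplarBank,
        cfg: DetectionConfig | None = None,
        tracker_cfg: TrackerConfig | None = None,
    ):
        self.bank = bank
        self.cfg = cfg or DetectionConfig()
        self.tracker_cfg = tracker_cfg or TrackerConfig()
        self.invocations = 0

    @property
    def self_match_score(self) -> float:
        """Mean self-similarity of the exemplars (1.0 for unit-norm features)."""
        if not self.bank.exemplars:
            raise ValueError("empty exemplar bank")
        return float(
            np.mean([np.sum(np.square(f.grid)) / max(np.sum(np.square(f.grid)), 1e-12) for f, _ in self.bank.exemplars])
        )

    def _coarse(self, grid: np.ndarray) -> np.ndarray:
        """Block-average a (C, n, n) feature grid and renormalize."""
        f = self.cfg.feature_downsample
        if f > 1:
            c, n, _ = grid.shape
            m = (n // f) * f
            grid = grid[:, :m, :m].reshape(c, m // f, f, m // f, f).mean(axis=(2, 4))
        norm = np.linalg.norm(grid)
        return grid / norm if norm > 1e-12 else grid

    def _exemplar_matrix(self) -> np.ndarray:
        return np.stack([self._coarse(f.grid).ravel() for f, _ in self.bank.exemplars])

    def _window_score(self, frame: FrameImage, cx: float, cy: float, w: float, h: float, mat: np.ndarray) -> float:
        tc = self.tracker_cfg
        feat, _, _ = make_template(frame, BBox.from_center(cx, cy, w, h), tc)
        v = self._coarse(feat.grid).ravel()
        return float(np.max(mat @ v))

    def detect(self, frame: FrameImage) -> Optional[tuple[BBox, float]]:
        """Scan the frame; return ``(box, score)`` or ``None``.

        The returned box has the bank's median exemplar size; the score is
        the best window's cosine similarity.
        """
        if not self.bank.exemplars:
            raise ValueError("cannot detect with an empty exemplar bank")
        self.invocations += 1
        w, h = self.bank.median_box_size
        mat = self._exemplar_matrix()
        stride = self.cfg.scan_stride
        xs = np.arange(w / 2.0, frame.width - w / 2.0 + 1e-9, stride)
        ys = np.arange(h / 2.0, frame.height - h / 2.0 + 1e-9, stride)
        if xs.size == 0:
            xs = np.array([frame.width / 2.0])
        if ys.size == 0:
            ys = np.array([frame.height / 2.0])
        coarse = sorted(
            ((self._window_score(frame, cx, cy, w, h, mat), cx, cy) for cy in ys for cx in xs),
            reverse=True,
        )
        # the correct basin is not always the coarse argmax (background
        # texture can edge it out at lattice misalignment), so refine the
        # top few coarse candidates with a two-stage local search
        best = coarse[0]
        r = self.cfg.refine_radius
        if r > 0 and stride > 1:
            for sc0, cx0, cy0 in coarse[:5]:
                local = (sc0, cx0, cy0)
                for step, rad in ((2, r), (1, 2)):
                    bx, by = local[1], local[2]
                    for dy in range(-rad, rad + 1, step):
                        for dx in range(-rad, rad + 1, step):
                            cx, cy = bx + dx, by + dy
                            if not (
                                w / 2 <= cx <= frame.width - w / 2
                                and h / 2 <= cy <= frame.height - h / 2
                            ):
                                continue
                            sc = self._window_score(frame, cx, cy, w, h, mat)
                            if sc > local[0]:
                                local = (sc, cx, cy)
                if local[0] > best[0]:
                    best = local
        score, cx, cy = best
        if score < self.cfg.accept_score_fraction * self.self_match_score:
            return None
        return BBox.from_center(cx, cy, w, h), float(score)

    def score_to_confidence(self, score: float) -> float:
        return float(np.clip(score / self.self_match_score, 0.0, 1.0))


def gated_step(
    state: TrackState,
    frame: FrameImage,
    cfg: TrackerConfig,
    detector: ExemplarDetector,
) -> tuple[TrackState, TrajectoryRecord]:
    """One tracking step with the confidence-gated detection fallback.

    Runs a normal step first.  If its confidence reaches the activation
    threshold (or the bank is empty), the step stands unchanged.  Otherwise
    the detector scans the frame: on success the current box is re-seeded
    to the detection, the distractor memory is cleared and the record is
    emitted with source ``detected``; on no-detection the tracker's own
    output is kept.
    """
    state, record = track_step(state, frame, cfg)
    if record.confidence >= detector.cfg.activation_threshold or len(detector.bank) == 0:
        return state, record
    found = detector.detect(frame)
    if found is None:
        return state, record
    box, score = found
    state.current_box = box
    state.distractors = []
    state.distractor_ages = []
    conf = detector.score_to_confidence(score)
    state.last_confidence = conf
    return state, TrajectoryRecord(
        frame_index=frame.index, box=box, confidence=conf, source=Source.DETECTED
    )


# --------------------------------------------------------------------------
# bank persistence: a .npz archive with an embedded JSON manifest


def save_bank(bank: ExemplarBank, path) -> None:
    if not bank.exemplars:
        raise ValueError("refusing to save an empty exemplar bank")
    grids = np.stack([f.grid for f, _ in bank.exemplars])
    strides = np.array([f.stride for f, _ in bank.exemplars])
    origins = np.array([f.origin for f, _ in bank.exemplars])
    sizes = np.array([s for _, s in bank.exemplars])
    manifest = json.dumps(
        {
            "n_exemplars": len(bank.exemplars),
            "feature_shape": list(grids.shape[1:]),
            "max_size": bank.max_size,
            "min_harvest_confidence": bank.min_harvest_confidence,
            "n_seen": bank.n_seen,
        }
    )
    np.savez(path, grids=grids, strides=strides, origins=origins, sizes=sizes,
             manifest=np.array(manifest))


def load_bank(path) -> ExemplarBank:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        exemplars = [
            (
                FeatureMap(grid=g, stride=float(st), origin=(float(o[0]), float(o[1]))),
                (float(s[0]), float(s[1])),
            )
            for g, st, o, s in zip(data["grids"], data["strides"], data["origins"], data["sizes"])
        ]
    return ExemplarBank(
        exemplars=exemplars,
        max_size=int(manifest["max_size"]),
        min_harvest_confidence=float(manifest["min_harvest_confidence"]),
        n_seen=int(manifest["n_seen"]),
    )
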