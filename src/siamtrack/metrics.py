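"""Evaluation criteria: overlap rate, pixel error and derived rates.

Overlap rate (OR) is intersection-over-union between the tracked and
ground-truth boxes; a frame is successful when OR >= the threshold
(default 0.5, inclusive at the boundary).  Pixel error (PE) is the
Euclidean distance between box centres; a frame is accurate when PE is
*strictly* below the threshold (default 20 px).  The error rate is the
complement of the success rate over the same frames and threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .correction import CorrectionLog, label_effort
from .types import BBox, Trajectory


def overlap_rate(a: BBox, b: BBox) -> float:
    """Intersection area over union area, under half-open box semantics."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    inter = max(0.0, ix) * max(0.0, iy)
    union = a.area + b.area - inter
    return inter / union


def pixel_error(result_center, truth_center) -> float:
    """Euclidean distance between two centres (boxes reduce to centres)."""
    if isinstance(result_center, BBox):
        result_center = result_center.center
    if isinstance(truth_center, BBox):
        truth_center = truth_center.center
    (x1, y1), (x2, y2) = result_center, truth_center
    for v in (x1, y1, x2, y2):
        if not math.isfinite(v):
            raise ValueError("pixel_error requires finite coordinates")
    return math.hypot(x1 - x2, y1 - y2)


@dataclass
class EvalReport:
    """Per-frame OR/PE series and the derived summary rates."""

    or_series: list[float] = field(default_factory=list)
    pe_series: list[float] = field(default_factory=list)
    success_rate: float = 0.0
    accuracy: float = 0.0
    error_rate: float = 0.0
    label_effort_percent: float = 0.0
    n_frames: int = 0
    n_missing_truth: int = 0
    or_threshold: float = 0.5
    pe_threshold: float = 20.0

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "n_missing_truth": self.n_missing_truth,
            "or_threshold": self.or_threshold,
            "pe_threshold": self.pe_threshold,
            "success_rate": self.success_rate,
            "error_rate": self.error_rate,
            "accuracy": self.accuracy,
            "label_effort_percent": self.label_effort_percent,
        }


def evaluate(
    traj: Trajectory,
    truth: dict[int, BBox],
    log: CorrectionLog | None = None,
    or_threshold: float = 0.5,
    pe_threshold: float = 20.0,
) -> EvalReport:
    """Score a trajectory against ground-truth boxes.

    Frames missing from the ground truth are excluded from the rates and
    counted in ``n_missing_truth``.  ``success_rate`` uses OR >= threshold
    (inclusive), ``accuracy`` uses PE < threshold (strict), and
    ``error_rate = 1 - success_rate`` exactly.
    """
    ors: list[float] = []
    pes: list[float] = []
    missing = 0
    for rec in traj.records:
        gt = truth.get(rec.frame_index)
        if gt is None:
            missing += 1
            continue
        ors.append(overlap_rate(rec.box, gt))
        pes.append(pixel_error(rec.box, gt))
    if not ors:
        raise ValueError("no trajectory frames overlap the ground-truth annotations")
    n = len(ors)
    success = sum(1 for v in ors if v >= or_threshold) / n
    accuracy = sum(1 for v in pes if v < pe_threshold) / n
    effort = label_effort(log) if log is not None and log.total_frames >= 1 else 0.0
    return EvalReport(
        or_series=ors,
        pe_series=pes,
        success_rate=success,
        accuracy=accuracy,
        error_rate=1.0 - success,
        label_effort_percent=effort,
        n_frames=n,
        n_missing_truth=missing,
        or_threshold=or_threshold,
        pe_threshold=pe_threshold,
    )


def box_size_sweep(
    traj: Trajectory,
    truth: dict[int, BBox],
    factors: Sequence[float] = (0.6, 0.8, 1.0, 1.2, 1.4),
    or_threshold: float = 0.5,
) -> dict[float, float]:
    """Success rate as a function of ground-truth box inflation/deflation.

    Re-evaluates with every truth box scaled about its centre by each
    factor — a sensitivity check on the bounding-box sizing convention
    (circumscribed rectangles, as tight as practical, are recommended).
    """
    out: dict[float, float] = {}
    for f in factors:
        if f <= 0:
            raise ValueError("scale factors must be positive")
        scaled = {k: b.scaled(f) for k, b in truth.items()}
        out[f] = evaluate(traj, scaled, or_threshold=or_threshold).success_rate
    return out
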