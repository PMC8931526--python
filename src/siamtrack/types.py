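"""Domain types shared across the tracker.

Coordinate conventions
----------------------
Images use a 0-based, origin-top-left frame: ``x`` runs along columns and
``y`` along rows.  A pixel at row ``r``, column ``c`` occupies the half-open
unit square ``[c, c+1) x [r, r+1)``, so its centre sits at ``(c + 0.5,
r + 0.5)`` in continuous coordinates.  Bounding boxes are ``(left, top,
width, height)`` and cover the half-open region ``[x, x+w) x [y, y+h)``;
with these semantics the area of a box is exactly ``w * h`` and two boxes
that share only an edge have zero intersection.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Source(str, enum.Enum):
    """Provenance of a per-frame tracking record."""

    AUTO = "auto"
    CORRECTED = "corrected"
    DETECTED = "detected"


@dataclass(frozen=True)
class BBox:
    """Axis-aligned rectangle in continuous pixel coordinates."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"BBox.{name} must be finite, got {v!r}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"BBox must have positive size, got w={self.w}, h={self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "BBox":
        return cls(cx - w / 2.0, cy - h / 2.0, w, h)

    def translated(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x + dx, self.y + dy, self.w, self.h)

    def scaled(self, factor: float) -> "BBox":
        """Box with the same centre and side lengths multiplied by ``factor``."""
        cx, cy = self.center
        return BBox.from_center(cx, cy, self.w * factor, self.h * factor)


@dataclass(frozen=True)
class FrameImage:
    """A single grayscale video frame with intensities in [0, 1]."""

    pixels: "object"  # 2-D float ndarray; kept loose to stay hashable-free
    index: int

    def __post_init__(self) -> None:
        import numpy as np

        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"FrameImage.pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"frame too small: {px.shape} (need at least 16x16)")
        if not np.all(np.isfinite(px)):
            raise ValueError("frame contains non-finite pixels")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("frame intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CorrectionEvent:
    """A human-supplied re-annotation at a given frame."""

    frame_index: int
    box: BBox

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")


@dataclass(frozen=True)
class TrajectoryRecord:
    frame_index: int
    box: BBox
    confidence: float
    source: Source

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0,1], got {self.confidence}")
        object.__setattr__(self, "source", Source(self.source))


@dataclass
class Trajectory:
    """Per-frame boxes, confidences and provenance for one tracked object."""

    records: list[TrajectoryRecord] = field(default_factory=list)
    video_id: str = ""

    def validate(self) -> None:
        if not self.records:
            raise ValueError("Trajectory must contain at least one record")
        if self.records[0].source is not Source.CORRECTED:
            raise ValueError("record 0 must have source 'corrected' (the initial annotation)")
        idx = [r.frame_index for r in self.records]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]
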