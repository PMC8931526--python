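"""Readers and writers for frames, trajectories and annotation CSVs.

Frame sequences are directories of PNG/JPEG images (ordered by plain
lexicographic filename sort -- zero-pad frame numbers) or a single
multi-frame stack file (e.g. multi-page TIFF).  Colour input is collapsed
to grayscale with fixed luma weights so results are reproducible.

Trajectory CSV:  ``frame,x,y,w,h,confidence,source``
Annotation CSV:  ``frame,x,y,w,h``
Both are UTF-8, comma-separated, header mandatory.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import BBox, FrameImage, Source, Trajectory, TrajectoryRecord

#: Fixed RGB->luma weights used for all colour conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    """Collapse an image array to float grayscale in [0, 1]."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(float) @ np.asarray(LUMA_WEIGHTS)
        else:
            arr = arr[:, :, 0].astype(float)
    else:
        arr = arr.astype(float)
    # integer-typed sources are normalized by their value range (8- or 16-bit)
    if arr.max() > 1.0:
        arr = arr / (255.0 if arr.max() <= 255.0 else 65535.0)
    return np.clip(arr, 0.0, 1.0)


def read_frame_sequence(path: str | os.PathLike) -> list[FrameImage]:
    """Read an ordered frame sequence from a directory or a stack file.

    Directory contents are ordered by plain lexicographic filename sort;
    multi-frame files keep their native frame order.  Indices are assigned
    0..N-1.  All frames must share one shape.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"frame source does not exist: {p}")
    arrays: list[np.ndarray] = []
    if p.is_dir():
        names = sorted(f for f in os.listdir(p) if Path(f).suffix.lower() in _IMAGE_EXTENSIONS)
        for name in names:
            arrays.append(_to_gray01(iio.imread(p / name)))
    else:
        stack = np.asarray(iio.imread(p))
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 4 or (stack.ndim == 3 and stack.shape[-1] in (3, 4)):
            # single colour image or colour stack
            if stack.ndim == 3:
                stack = stack[None]
            arrays = [_to_gray01(fr) for fr in stack]
        else:
            arrays = [_to_gray01(fr) for fr in stack]
    if not arrays:
        raise ValueError(f"no readable frames found in {p}")
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ValueError(f"frame {i} has shape {a.shape}, expected {shape}")
    return [FrameImage(pixels=a, index=i) for i, a in enumerate(arrays)]


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as CSV ``frame,x,y,w,h,confidence,source``."""
    traj.validate()
    df = pd.DataFrame(
        {
            "frame": [r.frame_index for r in traj.records],
            "x": [r.box.x for r in traj.records],
            "y": [r.box.y for r in traj.records],
            "w": [r.box.w for r in traj.records],
            "h": [r.box.h for r in traj.records],
            "confidence": [r.confidence for r in traj.records],
            "source": [r.source.value for r in traj.records],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_trajectory(path: str | os.PathLike, video_id: str = "") -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed trajectory CSV {path}: {exc}") from exc
    required = ["frame", "x", "y", "w", "h", "confidence", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV {path} missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                TrajectoryRecord(
                    frame_index=int(row["frame"]),
                    box=BBox(float(row["x"]), float(row["y"]), float(row["w"]), float(row["h"])),
                    confidence=float(row["confidence"]),
                    source=Source(str(row["source"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"bad trajectory row {i + 2} in {path}: {exc}") from exc
    traj = Trajectory(records=records, video_id=video_id)
    traj.validate()
    return traj


def read_annotations(path: str | os.PathLike) -> dict[int, BBox]:
    """Read a (possibly sparse) annotation CSV ``frame,x,y,w,h``."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed annotation CSV {path}: {exc}") from exc
    required = ["frame", "x", "y", "w", "h"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV {path} missing columns {missing}")
    out: dict[int, BBox] = {}
    for i, row in df.iterrows():
        frame = int(row["frame"])
        if frame in out:
            raise ValueError(f"duplicate frame index {frame} at row {i + 2} in {path}")
        w, h = float(row["w"]), float(row["h"])
        if w <= 0 or h <= 0:
            raise ValueError(f"non-positive box size at row {i + 2} in {path}: w={w}, h={h}")
        out[frame] = BBox(float(row["x"]), float(row["y"]), w, h)
    return out


def write_annotations(boxes: dict[int, BBox], path: str | os.PathLike) -> None:
    """Write an annotation CSV ``frame,x,y,w,h`` (frames sorted)."""
    frames = sorted(boxes)
    df = pd.DataFrame(
        {
            "frame": frames,
            "x": [boxes[f].x for f in frames],
            "y": [boxes[f].y for f in frames],
            "w": [boxes[f].w for f in frames],
            "h": [boxes[f].h for f in frames],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
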