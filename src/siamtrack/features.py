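"""Crop geometry, feature extraction and ROI-aligned resampling.

The template branch of the tracker crops a context-padded square around the
annotated box and resamples it to a fixed side (127 px by default); the
search branch does the same around the previous box at double the canonical
side (255 px).  Features are produced by a pluggable, registered extractor.
The default ``pix-grad`` extractor is deterministic and handcrafted:
locally mean-subtracted intensity plus horizontal/vertical gradients, each
box-smoothed, the whole map scaled to unit Frobenius norm.  It is
translation-equivariant with stride 1, which is the property the Siamese
matching machinery actually relies on; a learned backbone can be registered
under a different id without touching the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import ndimage

from .types import BBox, FrameImage


@dataclass(frozen=True)
class PatchTransform:
    """Affine map between patch coordinates and image coordinates.

    ``x_img = x0 + scale * x_patch`` (same scale on both axes; crops are
    square-to-square).  Patch coordinates are continuous, with patch pixel
    ``(r, c)`` centred at ``(c + 0.5, r + 0.5)``.
    """

    x0: float
    y0: float
    scale: float

    def to_image(self, xp: float, yp: float) -> tuple[float, float]:
        return (self.x0 + self.scale * xp, self.y0 + self.scale * yp)

    def to_patch(self, xi: float, yi: float) -> tuple[float, float]:
        return ((xi - self.x0) / self.scale, (yi - self.y0) / self.scale)

    def box_to_image(self, box: BBox) -> BBox:
        x, y = self.to_image(box.x, box.y)
        return BBox(x, y, box.w * self.scale, box.h * self.scale)


@dataclass(frozen=True)
class FeatureMap:
    """A channels x rows x cols feature grid anchored in image coordinates.

    ``stride`` is image pixels per feature cell; ``origin`` is the image
    coordinate of the centre of cell (0, 0).
    """

    grid: np.ndarray
    stride: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 3:
            raise ValueError(f"FeatureMap.grid must be 3-D (C,H,W), got {g.shape}")
        if not np.all(np.isfinite(g)):
            raise ValueError("FeatureMap contains non-finite values")
        if self.stride <= 0:
            raise ValueError("FeatureMap.stride must be positive")
        object.__setattr__(self, "grid", g)

    @property
    def channels(self) -> int:
        return self.grid.shape[0]

    @property
    def rows(self) -> int:
        return self.grid.shape[1]

    @property
    def cols(self) -> int:
        return self.grid.shape[2]

    def cell_center(self, row: float, col: float) -> tuple[float, float]:
        """Image coordinate of a (possibly fractional) cell position."""
        return (self.origin[0] + col * self.stride, self.origin[1] + row * self.stride)


def crop_side(box: BBox, context_factor: float) -> float:
    """Side of the context-padded square crop: sqrt((w+p)(h+p)), p = cf*(w+h)."""
    p = context_factor * (box.w + box.h)
    return math.sqrt((box.w + p) * (box.h + p))


def crop_and_resize(
    frame: FrameImage,
    box: BBox,
    context_factor: float,
    out_size: int,
    side: float | None = None,
) -> tuple[np.ndarray, PatchTransform]:
    """Crop a context-padded square around ``box`` and resample it.

    The crop is a square of side ``s = sqrt((w+p)(h+p))`` with
    ``p = context_factor*(w+h)`` centred on the box centre (``side``
    overrides ``s`` when given, which the search branch uses to scale its
    crop off the template geometry).  Out-of-frame regions are padded with
    the frame's mean intensity; resampling is bilinear.  Returns the patch
    and the affine patch<->image transform.
    """
    if out_size < 8:
        raise ValueError(f"out_size must be >= 8, got {out_size}")
    s = crop_side(box, context_factor) if side is None else float(side)
    cx, cy = box.center
    x0, y0 = cx - s / 2.0, cy - s / 2.0
    scale = s / out_size
    # patch pixel (r, c) centre -> image coord (x0 + (c+0.5)*scale, ...)
    idx = (np.arange(out_size) + 0.5) * scale
    xs = x0 + idx  # image x of each patch column centre
    ys = y0 + idx
    # continuous image coord -> array index: pixel (r,c) centre at (c+0.5, r+0.5)
    col_idx = xs - 0.5
    row_idx = ys - 0.5
    rr, cc = np.meshgrid(row_idx, col_idx, indexing="ij")
    mean = float(frame.pixels.mean())
    patch = ndimage.map_coordinates(
        frame.pixels, [rr, cc], order=1, mode="constant", cval=mean, prefilter=False
    )
    return patch, PatchTransform(x0=x0, y0=y0, scale=scale)


# --------------------------------------------------------------------------
# extractor registry

ExtractorFn = Callable[[np.ndarray, int], np.ndarray]

_EXTRACTORS: dict[str, ExtractorFn] = {}


def register_extractor(name: str, fn: ExtractorFn) -> None:
    """Register a feature extractor ``fn(patch, seed) -> (C, H, W) array``."""
    _EXTRACTORS[name] = fn


def available_extractors() -> list[str]:
    return sorted(_EXTRACTORS)


#: local window (px) for the mean-subtraction step of pix-grad
_LOCAL_MEAN_SIZE = 11


def _pix_grad(patch: np.ndarray, seed: int) -> np.ndarray:
    patch = np.asarray(patch, dtype=float)
    local_mean = ndimage.uniform_filter(patch, size=_LOCAL_MEAN_SIZE, mode="nearest")
    gy, gx = np.gradient(patch)
    chans = np.stack([patch - local_mean, gx, gy])
    chans = ndimage.uniform_filter(chans, size=(1, 3, 3), mode="nearest")
    norm = np.linalg.norm(chans)
    if norm > 1e-12:
        chans = chans / norm
    return chans


register_extractor("pix-grad", _pix_grad)


def extract_features(
    patch: np.ndarray,
    extractor_id: str = "pix-grad",
    seed: int = 0,
    transform: PatchTransform | None = None,
) -> FeatureMap:
    """Run a registered extractor on a square patch.

    Deterministic for fixed ``(patch, extractor_id, seed)``.  When the
    patch's :class:`PatchTransform` is supplied, the returned feature map is
    anchored in image coordinates; otherwise it lives in patch coordinates
    (stride 1, origin at the centre of patch pixel (0,0)).
    """
    if extractor_id not in _EXTRACTORS:
        raise KeyError(
            f"unknown extractor {extractor_id!r}; registered: {available_extractors()}"
        )
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square 2-D, got {patch.shape}")
    grid = _EXTRACTORS[extractor_id](patch, seed)
    if transform is None:
        return FeatureMap(grid=grid, stride=1.0, origin=(0.5, 0.5))
    ox, oy = transform.to_image(0.5, 0.5)
    return FeatureMap(grid=grid, stride=transform.scale, origin=(ox, oy))


def roi_align(
    fmap: FeatureMap, roi: BBox, out_rows: int, out_cols: int
) -> FeatureMap:
    """Bilinearly sample a feature map over an ROI given in image coordinates.

    Each output cell takes the bilinear sample of the input grid at the
    cell's centre, in continuous feature coordinates with no integer
    snapping (samples beyond the grid clamp to the edge cells).
    """
    if out_rows < 1 or out_cols < 1:
        raise ValueError("roi_align output size must be at least 1x1")
    # feature extent in image coords (outer edges of the border cells)
    ox, oy = fmap.origin
    x_lo, x_hi = ox - fmap.stride / 2, ox + (fmap.cols - 0.5) * fmap.stride
    y_lo, y_hi = oy - fmap.stride / 2, oy + (fmap.rows - 0.5) * fmap.stride
    if roi.x2 <= x_lo or roi.x >= x_hi or roi.y2 <= y_lo or roi.y >= y_hi:
        raise ValueError("roi is disjoint from the feature map's spatial extent")
    out_stride_x = roi.w / out_cols
    out_stride_y = roi.h / out_rows
    xs = roi.x + (np.arange(out_cols) + 0.5) * out_stride_x
    ys = roi.y + (np.arange(out_rows) + 0.5) * out_stride_y
    # image coord -> continuous feature cell index
    us = (xs - ox) / fmap.stride
    vs = (ys - oy) / fmap.stride
    vv, uu = np.meshgrid(vs, us, indexing="ij")
    coords = np.broadcast_arrays(
        np.arange(fmap.channels)[:, None, None],
        vv[None],
        uu[None],
    )
    out = ndimage.map_coordinates(
        fmap.grid, list(coords), order=1, mode="nearest", prefilter=False
    )
    out_stride = (out_stride_x + out_stride_y) / 2.0
    return FeatureMap(
        grid=out,
        stride=out_stride,
        origin=(roi.x + out_stride_x / 2.0, roi.y + out_stride_y / 2.0),
    )


def pool_feature_map(fmap: FeatureMap, out_rows: int, out_cols: int) -> FeatureMap:
    """Anti-aliased downsampling of a feature map to a coarser grid.

    Box-smooths each channel at the pooling scale, then ROI-aligns over the
    full extent.  Used to bring stride-1 pixel features down to the working
    correlation resolution.
    """
    factor = max(1, int(round(fmap.rows / out_rows)))
    grid = fmap.grid
    if factor > 1:
        grid = ndimage.uniform_filter(grid, size=(1, factor, factor), mode="nearest")
    smoothed = replace(fmap, grid=grid)
    full = BBox(
        fmap.origin[0] - fmap.stride / 2.0,
        fmap.origin[1] - fmap.stride / 2.0,
        fmap.cols * fmap.stride,
        fmap.rows * fmap.stride,
    )
    return roi_align(smoothed, full, out_rows, out_cols)
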