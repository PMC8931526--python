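"""Siamese matching core: correlation tracking with distractor suppression.

One tracking step crops a context-padded search region around the previous
box, extracts features, cross-correlates them with the (ROI-aligned)
template feature under a small bank of shape/scale candidates, subtracts
the correlation of remembered distractors, blends in a cosine motion
prior, and reads the new box off the winning peak.  The template is fixed
at the first annotation and only ever replaced by a human correction; the
output confidence is the softmax probability mass around the peak and
feeds both the correction workflow and the detection gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import fft as sfft
from scipy import ndimage, signal

from .features import (
    FeatureMap,
    crop_and_resize,
    crop_side,
    extract_features,
    pool_feature_map,
    roi_align,
)
from .types import BBox, CorrectionEvent, FrameImage, Source, Trajectory, TrajectoryRecord

__all__ = [
    "TrackerConfig",
    "ResponseMap",
    "TrackState",
    "cross_correlate",
    "window_energy",
    "normalize_response",
    "suppress_distractors",
    "locate_peak",
    "select_box_candidate",
    "compute_confidence",
    "make_template",
    "init_state",
    "track_step",
    "track_sequence",
]


@dataclass
class TrackerConfig:
    """All tunable knobs of the matching tracker (see docs/methods.md)."""

    template_size: int = 127
    search_size: int = 255
    context_factor: float = 0.5
    anchor_ratios: tuple[float, ...] = (1 / 3, 1 / 2, 1.0, 2.0, 3.0)
    scale_candidates: tuple[float, ...] = (0.96, 1.0, 1.04)
    window_weight: float = 0.35
    distractor_alpha: float = 0.5
    distractor_peak_fraction: float = 0.8
    distractor_memory: int = 5
    distractor_max_age: int = 2  # frames a mined feature stays usable
    confidence_temperature: float = 0.1
    size_damping: float = 0.3
    feature_cells: int = 24
    extractor_id: str = "pix-grad"
    extractor_seed: int = 0
    distractor_min_separation: Optional[int] = None  # cells; None = half box width
    # centre-weighted template: full weight over the annotated box, raised-
    # cosine falloff to this floor at the context edge (1.0 disables)
    template_taper_floor: float = 0.15

    def __post_init__(self) -> None:
        self.anchor_ratios = tuple(float(r) for r in self.anchor_ratios)
        self.scale_candidates = tuple(float(s) for s in self.scale_candidates)
        if self.template_size >= self.search_size:
            raise ValueError("template_size must be smaller than search_size")
        if len(self.anchor_ratios) != 5:
            raise ValueError("exactly 5 anchor ratios are required")
        if not (0.0 <= self.window_weight < 1.0):
            raise ValueError("window_weight must lie in [0, 1)")
        if self.distractor_alpha < 0:
            raise ValueError("distractor_alpha must be non-negative")
        if not (0.0 < self.distractor_peak_fraction < 1.0):
            raise ValueError("distractor_peak_fraction must lie in (0, 1)")
        if self.confidence_temperature <= 0:
            raise ValueError("confidence_temperature must be positive")
        if not (0.0 < self.size_damping <= 1.0):
            raise ValueError("size_damping must lie in (0, 1]")
        if self.feature_cells < 8:
            raise ValueError("feature_cells must be at least 8")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["anchor_ratios"] = list(self.anchor_ratios)
        d["scale_candidates"] = list(self.scale_candidates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrackerConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TrackerConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- derived geometry -------------------------------------------------
    @property
    def pool_stride(self) -> float:
        """Patch pixels per feature cell at the working resolution."""
        return self.template_size / self.feature_cells

    @property
    def search_cells(self) -> int:
        return int(round(self.search_size / self.pool_stride))


@dataclass(frozen=True)
class ResponseMap:
    """2-D similarity grid plus the mapping back to image coordinates.

    ``origin`` is the image coordinate of the window centre scored by cell
    (0, 0); ``stride`` is image pixels per cell.
    """

    scores: np.ndarray
    stride: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.size == 0:
            raise ValueError(f"ResponseMap.scores must be non-empty 2-D, got {s.shape}")
        if not np.all(np.isfinite(s)):
            raise ValueError("ResponseMap contains non-finite scores")
        object.__setattr__(self, "scores", s)

    @property
    def rows(self) -> int:
        return self.scores.shape[0]

    @property
    def cols(self) -> int:
        return self.scores.shape[1]

    def cell_center(self, row: float, col: float) -> tuple[float, float]:
        return (self.origin[0] + col * self.stride, self.origin[1] + row * self.stride)


@dataclass(frozen=True)
class CandidateSpec:
    """One (aspect-ratio, scale) box hypothesis scored by its own response."""

    ratio: float
    scale: float

    @property
    def fx(self) -> float:
        return self.scale * math.sqrt(self.ratio)

    @property
    def fy(self) -> float:
        return self.scale / math.sqrt(self.ratio)

    @property
    def id(self) -> str:
        return f"r={self.ratio:g},s={self.scale:g}"

    @property
    def is_identity(self) -> bool:
        return self.ratio == 1.0 and self.scale == 1.0


def candidate_specs(cfg: TrackerConfig) -> list[CandidateSpec]:
    """Candidates in tie-break order: identity first, then config order."""
    out = [CandidateSpec(1.0, 1.0)]
    for r in cfg.anchor_ratios:
        for s in cfg.scale_candidates:
            c = CandidateSpec(r, s)
            if not c.is_identity:
                out.append(c)
    return out


@dataclass
class TrackState:
    """Everything needed to advance the tracker by one frame."""

    template_feature: FeatureMap
    template_box: BBox
    current_box: BBox
    distractors: list[FeatureMap] = field(default_factory=list)
    distractor_ages: list[int] = field(default_factory=list)  # frames since mined
    last_confidence: float = 1.0
    template_box_cells: float = 0.0  # template box width at working resolution
    template_mask: Optional[np.ndarray] = None  # centre-weight taper (rows x cols)
    _candidate_cache: dict = field(default_factory=dict, repr=False)


# --------------------------------------------------------------------------
# correlation primitives


def _rfft_template(grid: np.ndarray, fshape: tuple[int, int]) -> np.ndarray:
    return sfft.rfftn(grid, fshape, axes=(1, 2)).conj()


def _fft_correlate(
    search_fft: np.ndarray,
    template_fft_conj: np.ndarray,
    tshape: tuple[int, int],
    sshape: tuple[int, int],
    fshape: tuple[int, int],
) -> np.ndarray:
    """Valid-mode multi-channel correlation in the frequency domain.

    For correlation no zero-padding beyond the search extent is needed:
    the valid offsets never wrap.  Channels are summed in the frequency
    domain so only one inverse transform runs per template.
    """
    prod = (search_fft * template_fft_conj).sum(axis=0)
    out = sfft.irfftn(prod, fshape)
    return out[: sshape[0] - tshape[0] + 1, : sshape[1] - tshape[1] + 1]


def _fft_correlate_2d(
    plane_fft: np.ndarray,
    kernel_fft_conj: np.ndarray,
    tshape: tuple[int, int],
    sshape: tuple[int, int],
    fshape: tuple[int, int],
) -> np.ndarray:
    """Single-plane valid-mode correlation (used for weighted window energy)."""
    out = sfft.irfftn(plane_fft * kernel_fft_conj, fshape)
    return out[: sshape[0] - tshape[0] + 1, : sshape[1] - tshape[1] + 1]


def cross_correlate(template_feat: FeatureMap, search_feat: FeatureMap) -> ResponseMap:
    """Valid-mode sliding inner product of template over search features.

    ``scores[i, j]`` sums ``template * search-window`` over all channels and
    template cells at offset ``(i, j)``; no padding.
    """
    t, s = template_feat.grid, search_feat.grid
    if t.shape[0] != s.shape[0]:
        raise ValueError(f"channel mismatch: template {t.shape[0]} vs search {s.shape[0]}")
    if t.shape[1] > s.shape[1] or t.shape[2] > s.shape[2]:
        raise ValueError(f"template {t.shape[1:]} larger than search {s.shape[1:]}")
    scores = signal.correlate(s, t, mode="valid")[0]
    tr, tc = t.shape[1], t.shape[2]
    origin = search_feat.cell_center((tr - 1) / 2.0, (tc - 1) / 2.0)
    return ResponseMap(scores=scores, stride=search_feat.stride, origin=origin)


def window_energy(search_feat: FeatureMap, rows: int, cols: int) -> np.ndarray:
    """Per-window feature energy ``sum(window**2)`` for all valid offsets.

    Computed with an integral image, so it is O(cells) regardless of the
    window size.
    """
    sq = np.square(search_feat.grid).sum(axis=0)
    h, w = sq.shape
    if rows > h or cols > w:
        raise ValueError(f"window {rows}x{cols} larger than feature grid {h}x{w}")
    ii = np.zeros((h + 1, w + 1))
    ii[1:, 1:] = sq.cumsum(axis=0).cumsum(axis=1)
    e = (
        ii[rows:, cols:]
        - ii[: h - rows + 1, cols:]
        - ii[rows:, : w - cols + 1]
        + ii[: h - rows + 1, : w - cols + 1]
    )
    return np.maximum(e, 0.0)


def normalize_response(resp: ResponseMap, energy: np.ndarray, eps: float = 1e-12) -> ResponseMap:
    """Divide raw correlation scores by the window feature norm.

    With a unit-norm template this turns the raw inner products into cosine
    similarities in [-1, 1], which is what the confidence softmax and the
    gating thresholds are calibrated against.
    """
    denom = np.sqrt(np.maximum(energy, eps))
    return replace(resp, scores=resp.scores / denom)


def suppress_distractors(
    resp: ResponseMap,
    search_feat: FeatureMap,
    distractors: Sequence[FeatureMap],
    alpha: float,
    energy: np.ndarray | None = None,
) -> ResponseMap:
    """Subtract the mean distractor correlation from a response map.

    ``scores' = scores - (alpha / max(1, k)) * sum_i corr(d_i, search)``.
    With ``alpha = 0`` or no distractors the input is returned unchanged.
    When ``energy`` is given, each distractor correlation is normalized by
    the same per-window energy as ``resp`` so both live on the same scale.
    """
    if alpha == 0.0 or not distractors:
        return resp
    total = np.zeros_like(resp.scores)
    for d in distractors:
        d_resp = cross_correlate(d, search_feat)
        d_scores = d_resp.scores
        if energy is not None:
            d_scores = d_scores / np.sqrt(np.maximum(energy, 1e-12))
        if d_scores.shape != resp.scores.shape:
            raise ValueError(
                f"distractor response shape {d_scores.shape} does not match {resp.scores.shape}"
            )
        total += d_scores
    out = resp.scores - (alpha / max(1, len(distractors))) * total
    return replace(resp, scores=out)


def _resample_scores(src: ResponseMap, like: ResponseMap) -> np.ndarray:
    """Bilinearly resample one response grid onto another's cell centres."""
    if src.scores.shape == like.scores.shape and src.origin == like.origin:
        return src.scores
    cols = (like.origin[0] - src.origin[0]) / src.stride + np.arange(like.cols) * (
        like.stride / src.stride
    )
    rows = (like.origin[1] - src.origin[1]) / src.stride + np.arange(like.rows) * (
        like.stride / src.stride
    )
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(src.scores, [rr, cc], order=1, mode="nearest", prefilter=False)


def _cosine_window(rows: int, cols: int, r0: int, c0: int) -> np.ndarray:
    """2-D raised cosine peaking at cell (r0, c0), zero at the map radius."""
    rr = np.abs(np.arange(rows) - r0) / max((rows - 1) / 2.0, 1.0)
    cc = np.abs(np.arange(cols) - c0) / max((cols - 1) / 2.0, 1.0)
    wr = 0.5 * (1.0 + np.cos(np.pi * np.minimum(rr, 1.0)))
    wc = 0.5 * (1.0 + np.cos(np.pi * np.minimum(cc, 1.0)))
    return wr[:, None] * wc[None, :]


def locate_peak(
    resp: ResponseMap,
    prev_center: tuple[float, float],
    window_weight: float,
    norm_bounds: tuple[float, float] | None = None,
) -> tuple[tuple[int, int], float, float]:
    """Find the peak of a response map under a cosine motion prior.

    Scores are min-max normalized to [0, 1] (bounds may be shared across
    several maps via ``norm_bounds``), then blended with a raised-cosine
    window centred on the cell nearest ``prev_center``.  Ties break to the
    smallest row, then smallest column.  An all-equal map degenerates to
    the centre cell.  Returns ``(peak_cell, windowed_score, raw_score)``.
    """
    s = resp.scores
    smin, smax = (float(s.min()), float(s.max())) if norm_bounds is None else norm_bounds
    if smax - smin < 1e-12 and window_weight == 0.0:
        r0, c0 = resp.rows // 2, resp.cols // 2
        return (r0, c0), 0.0, float(s[r0, c0])
    s_norm = (s - smin) / (smax - smin) if smax > smin else np.zeros_like(s)
    c0 = int(np.clip(round((prev_center[0] - resp.origin[0]) / resp.stride), 0, resp.cols - 1))
    r0 = int(np.clip(round((prev_center[1] - resp.origin[1]) / resp.stride), 0, resp.rows - 1))
    blended = (1.0 - window_weight) * s_norm + window_weight * _cosine_window(
        resp.rows, resp.cols, r0, c0
    )
    flat = int(np.argmax(blended))  # row-major first maximum = tie-break rule
    peak = (flat // resp.cols, flat % resp.cols)
    return peak, float(blended[peak]), float(s[peak])


def select_box_candidate(
    responses: Sequence[tuple[CandidateSpec, ResponseMap]],
    prev_box: BBox,
    size_damping: float,
    window_weight: float = 0.0,
    frame_size: tuple[int, int] | None = None,
) -> tuple[BBox, str]:
    """Pick the winning (ratio, scale) candidate and assemble the new box.

    Every candidate's map is windowed and peak-scored under one *shared*
    min-max normalization (so between-candidate score differences survive);
    the winner is the highest windowed peak, ties broken by candidate
    order with the identity candidate first.  The new centre is the image
    coordinate of the winning peak; the new size is the previous size
    blended with the winner's hypothesised size by ``size_damping``.  The
    centre is clamped inside the frame when ``frame_size`` is given.
    """
    if not responses:
        raise ValueError("empty candidate set")
    prev_center = prev_box.center
    lo = min(float(r.scores.min()) for _, r in responses)
    hi = max(float(r.scores.max()) for _, r in responses)
    best = None
    for cand, resp in responses:
        peak, wscore, _ = locate_peak(resp, prev_center, window_weight, norm_bounds=(lo, hi))
        if best is None or wscore > best[0]:
            best = (wscore, cand, resp, peak)
    _, cand, resp, peak = best
    cx, cy = resp.cell_center(*peak)
    w_hyp = cand.fx * prev_box.w
    h_hyp = cand.fy * prev_box.h
    w_new = (1.0 - size_damping) * prev_box.w + size_damping * w_hyp
    h_new = (1.0 - size_damping) * prev_box.h + size_damping * h_hyp
    if frame_size is not None:
        h_img, w_img = frame_size
        cx = float(np.clip(cx, 0.5, w_img - 0.5))
        cy = float(np.clip(cy, 0.5, h_img - 0.5))
    return BBox.from_center(cx, cy, w_new, h_new), cand.id


def compute_confidence(resp: ResponseMap, temperature: float) -> float:
    """Softmax probability mass in the 3x3 neighbourhood of the peak.

    ``p = softmax(scores / temperature)`` over all cells; the confidence is
    the summed mass over the 3x3 block around the argmax (clipped at the
    borders).  Ties in the argmax resolve to the cell nearest the map
    centre, so a constant N-cell map gives exactly ``min(9, N) / N``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s = resp.scores
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite scores")
    z = s / temperature
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    maxima = np.argwhere(s == s.max())
    center = np.array([(resp.rows - 1) / 2.0, (resp.cols - 1) / 2.0])
    d2 = ((maxima - center) ** 2).sum(axis=1)
    r, c = maxima[int(np.argmin(d2))]
    block = p[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
    return float(block.sum())


# --------------------------------------------------------------------------
# template handling and the per-frame step


def _taper_1d(n: int, inner_cells: float, floor: float) -> np.ndarray:
    """Raised-cosine centre weight: 1 over the inner span, ``floor`` at the edge."""
    if floor >= 1.0:
        return np.ones(n)
    c = (n - 1) / 2.0
    rho = np.abs(np.arange(n) - c) / (n / 2.0)
    rho0 = float(np.clip(1.1 * inner_cells / n, 0.05, 0.9))
    ramp = np.clip((rho - rho0) / (1.0 - rho0), 0.0, 1.0)
    return floor + (1.0 - floor) * 0.5 * (1.0 + np.cos(np.pi * ramp))


def template_taper(cfg: TrackerConfig, box: BBox) -> np.ndarray:
    """Centre-weight mask for a template of ``cfg.feature_cells`` cells.

    Full weight over the annotated box, cosine falloff to
    ``template_taper_floor`` toward the context edge.  Damping the context
    keeps a template honest about what the user annotated: a bright object
    that happens to sit in the crop's margin (the classic identical-twin
    hazard) cannot dominate the match.
    """
    s_z = crop_side(box, cfg.context_factor)
    n = cfg.feature_cells
    wx = box.w / s_z * cfg.template_size / cfg.pool_stride
    wy = box.h / s_z * cfg.template_size / cfg.pool_stride
    return _taper_1d(n, wy, cfg.template_taper_floor)[:, None] * _taper_1d(
        n, wx, cfg.template_taper_floor
    )[None, :]


def make_template(
    frame: FrameImage, box: BBox, cfg: TrackerConfig
) -> tuple[FeatureMap, float, np.ndarray]:
    """Extract the pooled, centre-weighted, unit-norm template feature.

    Returns the feature map, the box width in feature cells at the working
    resolution (distractor bookkeeping), and the taper mask used.
    """
    patch, tf = crop_and_resize(frame, box, cfg.context_factor, cfg.template_size)
    feat = extract_features(patch, cfg.extractor_id, cfg.extractor_seed, transform=tf)
    pooled = pool_feature_map(feat, cfg.feature_cells, cfg.feature_cells)
    mask = template_taper(cfg, box)
    grid = pooled.grid * mask
    norm = np.linalg.norm(grid)
    grid = grid / norm if norm > 1e-12 else grid
    s_z = crop_side(box, cfg.context_factor)
    box_cells = box.w / s_z * cfg.template_size / cfg.pool_stride
    return replace(pooled, grid=grid), box_cells, mask


def init_state(frame: FrameImage, box: BBox, cfg: TrackerConfig) -> TrackState:
    """Build the initial tracker state from the first-frame annotation."""
    tmpl, box_cells, mask = make_template(frame, box, cfg)
    return TrackState(
        template_feature=tmpl,
        template_box=box,
        current_box=box,
        distractors=[],
        last_confidence=1.0,
        template_box_cells=box_cells,
        template_mask=mask,
    )


def _unit(fmap: FeatureMap) -> FeatureMap:
    n = np.linalg.norm(fmap.grid)
    return replace(fmap, grid=fmap.grid / n) if n > 1e-12 else fmap


def _candidate_templates(
    state: TrackState, cfg: TrackerConfig, fshape: tuple[int, int]
) -> list[tuple[CandidateSpec, FeatureMap, np.ndarray]]:
    """Template features stretched to each (ratio, scale) hypothesis.

    Cached on the state together with their conjugate FFTs — they only
    change when a correction replaces the template.
    """
    key = (cfg.anchor_ratios, cfg.scale_candidates, cfg.feature_cells, fshape)
    if state._candidate_cache.get("key") == key:
        return state._candidate_cache["templates"]
    tmpl = state.template_feature
    full = BBox(
        tmpl.origin[0] - tmpl.stride / 2.0,
        tmpl.origin[1] - tmpl.stride / 2.0,
        tmpl.cols * tmpl.stride,
        tmpl.rows * tmpl.stride,
    )
    base_mask = (
        state.template_mask
        if state.template_mask is not None
        else np.ones((tmpl.rows, tmpl.cols))
    )
    mask_map = FeatureMap(grid=base_mask[None], stride=tmpl.stride, origin=tmpl.origin)
    out = []
    for cand in candidate_specs(cfg):
        if cand.is_identity:
            t, m = tmpl, base_mask
        else:
            rows = int(np.clip(round(tmpl.rows * cand.fy), 4, cfg.search_cells - 1))
            cols = int(np.clip(round(tmpl.cols * cand.fx), 4, cfg.search_cells - 1))
            t = _unit(roi_align(tmpl, full, rows, cols))
            m = roi_align(mask_map, full, rows, cols).grid[0]
        m2_fft = sfft.rfftn(np.square(m), fshape).conj()
        out.append((cand, t, _rfft_template(t.grid, fshape), m2_fft))
    state._candidate_cache["templates"] = out
    state._candidate_cache["key"] = key
    return out


def _mine_distractors(
    state: TrackState,
    cfg: TrackerConfig,
    ncc: ResponseMap,
    search_feat: FeatureMap,
    primary_cell: tuple[int, int],
) -> None:
    """Append secondary-peak features to the distractor memory.

    The primary peak is the location the tracker just chose as the target
    (not the raw argmax: with an identical distractor nearby the raw
    argmax can sit on the distractor, and mining relative to it would
    memorise the target itself).  Secondary peaks are 3x3 local maxima of
    the identity-candidate map with raw score >=
    distractor_peak_fraction * the primary score, at least a minimum cell
    separation from the primary (by default half the template box width
    in cells; the response map is too small for anything farther to
    exist).  The newest features are kept; the oldest are evicted beyond
    the memory size.
    """
    s = ncc.scores
    pr, pc = primary_cell
    # the score floor references the top raw peak, not the chosen cell: when
    # the target is weak (dim, occluded) the chosen score is low and a floor
    # relative to it would let background ripples flood the memory
    primary = float(s.max())
    if primary <= 0:
        return
    min_sep = cfg.distractor_min_separation
    if min_sep is None:
        min_sep = max(2, int(round(state.template_box_cells / 2.0)))
    local_max = s >= ndimage.maximum_filter(s, size=3, mode="constant", cval=-np.inf)
    cand_cells = np.argwhere(local_max & (s >= cfg.distractor_peak_fraction * primary))
    order = np.argsort([-s[r, c] for r, c in cand_cells], kind="stable")
    accepted: list[tuple[int, int]] = [(pr, pc)]
    new_feats: list[FeatureMap] = []
    tmpl = state.template_feature
    half_w = tmpl.cols * search_feat.stride / 2.0
    half_h = tmpl.rows * search_feat.stride / 2.0
    for idx in order:
        r, c = int(cand_cells[idx][0]), int(cand_cells[idx][1])
        if all(math.hypot(r - ar, c - ac) >= min_sep for ar, ac in accepted):
            accepted.append((r, c))
            cx, cy = ncc.cell_center(r, c)
            roi = BBox(cx - half_w, cy - half_h, 2 * half_w, 2 * half_h)
            feat = roi_align(search_feat, roi, tmpl.rows, tmpl.cols)
            if state.template_mask is not None:
                feat = replace(feat, grid=feat.grid * state.template_mask)
            new_feats.append(_unit(feat))
    if new_feats:
        state.distractors = (new_feats + state.distractors)[: cfg.distractor_memory]
        state.distractor_ages = ([0] * len(new_feats) + state.distractor_ages)[: cfg.distractor_memory]


def track_step(
    state: TrackState, frame: FrameImage, cfg: TrackerConfig
) -> tuple[TrackState, TrajectoryRecord]:
    """Advance the tracker by one frame (mutates and returns ``state``).

    The template is never updated here; only a correction (or a detector
    re-seed of the position) changes what the tracker is looking for.
    """
    box = state.current_box
    # age out stale distractor snapshots: a crossing distractor moves, so an
    # old snapshot anchors suppression at a position the target may now occupy
    if state.distractors:
        state.distractor_ages = [a + 1 for a in state.distractor_ages]
        keep = [i for i, a in enumerate(state.distractor_ages) if a <= cfg.distractor_max_age]
        state.distractors = [state.distractors[i] for i in keep]
        state.distractor_ages = [state.distractor_ages[i] for i in keep]
    s_z = crop_side(box, cfg.context_factor)
    side = s_z * cfg.search_size / cfg.template_size
    patch, tf = crop_and_resize(frame, box, cfg.context_factor, cfg.search_size, side=side)
    feat = extract_features(patch, cfg.extractor_id, cfg.extractor_seed, transform=tf)
    search_feat = pool_feature_map(feat, cfg.search_cells, cfg.search_cells)
    sshape = (search_feat.rows, search_feat.cols)
    fshape = (sfft.next_fast_len(sshape[0]), sfft.next_fast_len(sshape[1]))
    search_fft = sfft.rfftn(search_feat.grid, fshape, axes=(1, 2))
    sq_fft = sfft.rfftn(np.square(search_feat.grid).sum(axis=0), fshape)

    responses: list[tuple[CandidateSpec, ResponseMap]] = []
    identity_ncc: ResponseMap | None = None
    identity_energy: np.ndarray | None = None
    for cand, tmpl_c, tfft, m2_fft in _candidate_templates(state, cfg, fshape):
        shape = (tmpl_c.rows, tmpl_c.cols)
        # window energy weighted by the (stretched) template taper, so the
        # normalized score is a true cosine in the taper-weighted space
        energy = _fft_correlate_2d(sq_fft, m2_fft, shape, sshape, fshape)
        scores = _fft_correlate(search_fft, tfft, shape, sshape, fshape)
        origin = search_feat.cell_center((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        raw = ResponseMap(scores=scores, stride=search_feat.stride, origin=origin)
        ncc = normalize_response(raw, energy)
        if cand.is_identity:
            identity_ncc, identity_energy = ncc, energy
        responses.append((cand, ncc))

    # distractor suppression (shared mean-distractor map, resampled per shape)
    if cfg.distractor_alpha > 0 and state.distractors:
        tmpl = state.template_feature
        tshape = (tmpl.rows, tmpl.cols)
        denom = np.sqrt(np.maximum(identity_energy, 1e-12))
        d_total = np.zeros_like(identity_ncc.scores)
        for d in state.distractors:
            d_total += _fft_correlate(search_fft, _rfft_template(d.grid, fshape), tshape, sshape, fshape) / denom
        d_mean = d_total / len(state.distractors)
        suppressed = []
        for cand, ncc in responses:
            d_scores = _resample_scores(replace(identity_ncc, scores=d_mean), ncc)
            suppressed.append((cand, replace(ncc, scores=ncc.scores - cfg.distractor_alpha * d_scores)))
        scored = suppressed
    else:
        scored = responses

    new_box, cand_id = select_box_candidate(
        scored,
        box,
        cfg.size_damping,
        window_weight=cfg.window_weight,
        frame_size=(frame.height, frame.width),
    )
    # confidence reflects the match quality of the chosen location, so it is
    # read off the *unsuppressed* winning map (suppression rescales the whole
    # peak neighbourhood and would depress it even when tracking is clean)
    win_resp = next(r for c, r in responses if c.id == cand_id)
    confidence = float(np.clip(compute_confidence(win_resp, cfg.confidence_temperature), 0.0, 1.0))

    if cfg.distractor_alpha > 0:
        cx, cy = new_box.center
        pr = int(np.clip(round((cy - identity_ncc.origin[1]) / identity_ncc.stride), 0, identity_ncc.rows - 1))
        pc = int(np.clip(round((cx - identity_ncc.origin[0]) / identity_ncc.stride), 0, identity_ncc.cols - 1))
        _mine_distractors(state, cfg, identity_ncc, search_feat, (pr, pc))

    state.current_box = new_box
    state.last_confidence = confidence
    record = TrajectoryRecord(
        frame_index=frame.index, box=new_box, confidence=confidence, source=Source.AUTO
    )
    return state, record


def track_sequence(
    frames: Sequence[FrameImage],
    initial_box: BBox,
    cfg: TrackerConfig | None = None,
    corrections: Sequence[CorrectionEvent] = (),
    detector=None,
    video_id: str = "",
    seed: int = 0,
) -> Trajectory:
    """Track a whole frame sequence from a first-frame annotation.

    Corrections matching a frame index replace the template and the box at
    that frame (source ``corrected``, confidence 1.0).  A correction at
    frame 0 is ignored in favour of ``initial_box`` (the initial
    annotation wins).  When a detector is supplied, low-confidence steps
    are routed through its confidence gate (see :mod:`siamtrack.detection`).
    The whole pipeline is deterministic for fixed inputs and seed.
    """
    from .correction import apply_correction
    from .detection import gated_step

    if len(frames) == 0:
        raise ValueError("frames must be non-empty")
    cfg = cfg or TrackerConfig()
    by_frame = {}
    for ev in corrections:
        if ev.frame_index >= len(frames):
            raise ValueError(f"correction at frame {ev.frame_index} beyond sequence end")
        if ev.frame_index == 0:
            continue  # initial_box wins; documented precedence
        by_frame[ev.frame_index] = ev.box

    state = init_state(frames[0], initial_box, cfg)
    records = [
        TrajectoryRecord(
            frame_index=frames[0].index, box=initial_box, confidence=1.0, source=Source.CORRECTED
        )
    ]
    for frame in frames[1:]:
        if frame.index in by_frame:
            box = by_frame[frame.index]
            state = apply_correction(state, frame, box, cfg)
            records.append(
                TrajectoryRecord(
                    frame_index=frame.index, box=box, confidence=1.0, source=Source.CORRECTED
                )
            )
            continue
        if detector is not None:
            state, record = gated_step(state, frame, cfg, detector)
        else:
            state, record = track_step(state, frame, cfg)
        records.append(record)
    traj = Trajectory(records=records, video_id=video_id)
    traj.validate()
    return traj
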