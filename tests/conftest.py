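import numpy as np
import pytest

from siamtrack import BBox, FrameImage


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textured_frame(rng):
    """A 64x64 frame with smooth texture and a bright disc at (40, 24)."""
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.standard_normal((64, 64)), 3.0)
    img = img / np.abs(img).max() * 0.08 + 0.35
    yy, xx = np.mgrid[0:64, 0:64]
    d = np.hypot(xx + 0.5 - 40.0, yy + 0.5 - 24.0)
    img = img * 1.0 + np.clip(10.0 - d + 0.5, 0, 1) * 0.4
    return FrameImage(pixels=np.clip(img, 0, 1), index=0)


def brute_force_correlate(template, search):
    """Triple-loop valid-mode correlation oracle (channels x rows x cols)."""
    c, th, tw = template.shape
    _, sh, sw = search.shape
    out = np.zeros((sh - th + 1, sw - tw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            acc = 0.0
            for ch in range(c):
                acc += float(np.sum(template[ch] * search[ch, i : i + th, j : j + tw]))
            out[i, j] = acc
    return out


def brute_force_bilinear(grid, v, u):
    """Per-point bilinear sample of a 2-D grid with edge clamping."""
    h, w = grid.shape
    v = min(max(v, 0.0), h - 1.0)
    u = min(max(u, 0.0), w - 1.0)
    v0, u0 = int(np.floor(v)), int(np.floor(u))
    v1, u1 = min(v0 + 1, h - 1), min(u0 + 1, w - 1)
    fv, fu = v - v0, u - u0
    return (
        grid[v0, u0] * (1 - fv) * (1 - fu)
        + grid[v0, u1] * (1 - fv) * fu
        + grid[v1, u0] * fv * (1 - fu)
        + grid[v1, u1] * fv * fu
    )


def rasterized_iou(a: BBox, b: BBox, scale: int = 1):
    """Pixel-count IoU oracle for integer-coordinate boxes."""
    x_hi = int(max(a.x2, b.x2)) + 2
    y_hi = int(max(a.y2, b.y2)) + 2
    xx, yy = np.meshgrid(np.arange(x_hi), np.arange(y_hi))
    in_a = (xx >= a.x) & (xx < a.x2) & (yy >= a.y) & (yy < a.y2)
    in_b = (xx >= b.x) & (xx < b.x2) & (yy >= b.y) & (yy < b.y2)
    inter = np.sum(in_a & in_b)
    union = np.sum(in_a | in_b)
    return inter / union
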