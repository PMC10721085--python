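"""Feature detection and tracking: the "read head" of the physical reservoir.

Corners are detected on the first luminance frame with the Shi-Tomasi
criterion (smallest eigenvalue of the local structure tensor), thinned by
a minimum-distance rule, and then followed through the clip with iterative
pyramidal Lucas-Kanade optical flow.  The tracked (x, y) trajectories form
the reservoir state matrix X: one column per coordinate, one row per frame.

Conventions: images are row-major with origin at the top-left; x indexes
columns, y indexes rows; coordinates are 0-based and subpixel positions are
read with bilinear interpolation.  Image derivatives are central differences
with edge replication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .video import VideoClip, clip_to_luminance, pool_clip
from . import _kernels


@dataclass
class DetectionConfig:
    """Shi-Tomasi corner detection parameters.

    patch_size is the side of the square patch over which the structure
    tensor is accumulated (7 px); min_distance is the smallest allowed
    Euclidean distance between two accepted points (20 px); candidates
    must exceed quality_fraction * R_max, where R_max is the largest
    corner response in the image.  harris_k is only used in "harris"
    response mode (R = det(A) - k * trace(A)^2).
    """

    patch_size: int = 7
    min_distance: float = 20.0
    quality_fraction: float = 0.01
    harris_k: float = 0.04
    response_mode: str = "shi_tomasi"

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if not (0 < self.quality_fraction <= 1):
            raise ValueError("quality_fraction must be in (0, 1]")
        if self.response_mode not in ("shi_tomasi", "harris"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")


@dataclass
class FlowConfig:
    """Pyramidal Lucas-Kanade parameters.

    window_size x window_size pixels around each point constrain the flow
    (15); pyramid_levels m gives m extra quarter-area levels on top of the
    full-resolution one (3); the per-level solve is refined iteratively up
    to max_iterations or until the update falls below update_epsilon px.
    A point whose spatial-gradient matrix A^T A has smallest eigenvalue
    below min_eigen_threshold is declared lost.
    """

    window_size: int = 15
    pyramid_levels: int = 3
    max_iterations: int = 10
    update_epsilon: float = 0.01
    min_eigen_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.pyramid_levels < 0:
            raise ValueError("pyramid_levels must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class FeaturePoint:
    id: int
    x: float
    y: float
    response: float


@dataclass
class ReservoirSeries:
    """Tracked trajectories as an N x M state matrix.

    Columns are interleaved (x_1, y_1, x_2, y_2, ...), so M = 2 * number
    of feature points and each "reservoir unit" is one coordinate of one
    point.  lost_mask[n, k] is True while point k is tracked at step n;
    after a loss the coordinates are frozen at the last valid value so X
    stays rectangular.
    """

    X: np.ndarray
    point_ids: np.ndarray
    fps: float = 60.0
    lost_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] % 2 != 0:
            raise ValueError("X must be N x M with even M")
        self.point_ids = np.asarray(self.point_ids)
        if self.point_ids.size != self.X.shape[1] // 2:
            raise ValueError("point_ids length must be M/2")
        if self.lost_mask is None:
            self.lost_mask = np.ones((self.X.shape[0], self.point_ids.size), bool)

    @property
    def n_steps(self) -> int:
        return self.X.shape[0]

    @property
    def n_units(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path, meta: dict | None = None) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols: dict[str, np.ndarray] = {"t": np.arange(self.n_steps)}
        for j, pid in enumerate(self.point_ids):
            cols[f"p{pid}_x"] = self.X[:, 2 * j]
            cols[f"p{pid}_y"] = self.X[:, 2 * j + 1]
        pd.DataFrame(cols).to_csv(path, index=False)
        sidecar = {"fps": self.fps,
                   "point_ids": [int(p) for p in self.point_ids],
                   "lost_mask": self.lost_mask.astype(int).tolist()}
        if meta:
            sidecar.update(meta)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReservoirSeries":
        path = Path(path)
        df = pd.read_csv(path)
        coord_cols = [c for c in df.columns if c != "t"]
        pids = sorted({int(c.split("_")[0][1:]) for c in coord_cols})
        X = df[[f"p{p}_{ax}" for p in pids for ax in ("x", "y")]].to_numpy(float)
        fps, lost = 60.0, None
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fps = float(meta.get("fps", 60.0))
            if "lost_mask" in meta:
                lost = np.asarray(meta["lost_mask"], bool)
        return cls(X, np.asarray(pids), fps=fps, lost_mask=lost)


# ---------------------------------------------------------------------------
# gradients, structure tensor, corner response
# ---------------------------------------------------------------------------


def central_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(Ix, Iy): central differences with replicated edges."""
    img = np.asarray(img, float)
    p = np.pad(img, 1, mode="edge")
    ix = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    iy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    return ix, iy


def structure_tensor(img: np.ndarray, center: tuple[float, float],
                     patch_size: int = 7) -> np.ndarray:
    """2x2 structure tensor summed over a patch_size patch at *center*.

    center is (x, y) in pixel coordinates; the patch must lie fully inside
    the image.  Returns [[sum Ix^2, sum IxIy], [sum IxIy, sum Iy^2]].
    """
    img = np.asarray(img, float)
    h, w = img.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    r = patch_size // 2
    if not (r <= cx < w - r and r <= cy < h - r):
        raise ValueError(f"patch at ({cx}, {cy}) exceeds image bounds {w}x{h}")
    ix, iy = central_gradients(img)
    sl = np.s_[cy - r: cy + r + 1, cx - r: cx + r + 1]
    a = float((ix[sl] ** 2).sum())
    b = float((ix[sl] * iy[sl]).sum())
    c = float((iy[sl] ** 2).sum())
    return np.array([[a, b], [b, c]])


def corner_response(A: np.ndarray, mode: str = "shi_tomasi",
                    k: float = 0.04) -> float:
    """Scalar corner response of a 2x2 structure tensor.

    shi_tomasi: min eigenvalue; harris: det(A) - k * trace(A)^2.
    """
    A = np.asarray(A, float)
    a, b, c = A[0, 0], A[0, 1], A[1, 1]
    if mode == "harris":
        return float(a * c - b * b - k * (a + c) ** 2)
    if mode == "shi_tomasi":
        return float((a + c) / 2 - np.sqrt(((a - c) / 2) ** 2 + b * b))
    raise ValueError(f"unknown mode {mode!r}")


def corner_response_map(img: np.ndarray, patch_size: int = 7,
                        mode: str = "shi_tomasi", k: float = 0.04) -> np.ndarray:
    """Corner response at every pixel (patch sums via a uniform filter)."""
    img = np.asarray(img, float)
    ix, iy = central_gradients(img)
    n = patch_size * patch_size
    sxx = ndimage.uniform_filter(ix * ix, patch_size, mode="constant") * n
    sxy = ndimage.uniform_filter(ix * iy, patch_size, mode="constant") * n
    syy = ndimage.uniform_filter(iy * iy, patch_size, mode="constant") * n
    if mode == "harris":
        return sxx * syy - sxy ** 2 - k * (sxx + syy) ** 2
    half_tr = (sxx + syy) / 2
    return half_tr - np.sqrt(((sxx - syy) / 2) ** 2 + sxy ** 2)


def detect_features(img: np.ndarray,
                    cfg: DetectionConfig | None = None) -> list[FeaturePoint]:
    """Shi-Tomasi corners thinned by the minimum-distance rule.

    Candidates with response above quality_fraction * R_max are visited in
    decreasing response order (ties broken by (y, x)) and greedily accepted
    if at least min_distance away from every already accepted point, so the
    result is deterministic.  A blank image yields an empty list.
    """
    cfg = cfg or DetectionConfig()
    img = np.asarray(img, float)
    if min(img.shape) < cfg.patch_size:
        raise ValueError("image smaller than detection patch")
    resp = corner_response_map(img, cfg.patch_size, cfg.response_mode, cfg.harris_k)
    margin = cfg.patch_size // 2
    interior = np.full(resp.shape, False)
    interior[margin:-margin or None, margin:-margin or None] = True
    resp = np.where(interior, resp, -np.inf)
    r_max = resp.max()
    if not np.isfinite(r_max) or r_max <= 0:
        return []
    ys, xs = np.nonzero(resp > cfg.quality_fraction * r_max)
    vals = resp[ys, xs]
    order = np.lexsort((xs, ys, -vals))  # response desc, then (y, x)
    kept: list[FeaturePoint] = []
    kx = np.empty(0)
    ky = np.empty(0)
    min_d2 = cfg.min_distance ** 2
    for idx in order:
        x, y = xs[idx], ys[idx]
        if kept and np.min((kx - x) ** 2 + (ky - y) ** 2) < min_d2:
            continue
        kept.append(FeaturePoint(len(kept), float(x), float(y), float(vals[idx])))
        kx = np.append(kx, float(x))
        ky = np.append(ky, float(y))
    return kept


# ---------------------------------------------------------------------------
# Gaussian pyramid and Lucas-Kanade flow
# ---------------------------------------------------------------------------

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def gaussian_pyramid(img: np.ndarray, m: int) -> list[np.ndarray]:
    """[level 0 .. level m]; each level blurred and decimated 2x per axis.

    Level l has 1/4^l the area of the input.  Blur is a separable 5-tap
    binomial kernel (a standard discrete Gaussian approximation).
    """
    img = np.asarray(img)
    if img.dtype not in (np.float32, np.float64):
        img = img.astype(np.float64)
    levels = [img]
    kernel = _BINOMIAL5.astype(img.dtype)
    for _ in range(m):
        prev = levels[-1]
        if min(prev.shape) < 4:
            raise ValueError(f"image too small for {m} pyramid levels")
        blurred = ndimage.correlate1d(prev, kernel, axis=0, mode="nearest")
        blurred = ndimage.correlate1d(blurred, kernel, axis=1, mode="nearest")
        levels.append(np.ascontiguousarray(blurred[::2, ::2]))
    return levels


def _bilinear(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Sample img at float coordinates with edge clamping."""
    h, w = img.shape
    ys = np.clip(ys, 0.0, h - 1.0)
    xs = np.clip(xs, 0.0, w - 1.0)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 2) if h > 1 else np.zeros_like(ys, int)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 2) if w > 1 else np.zeros_like(xs, int)
    fy = ys - y0
    fx = xs - x0
    tl = img[y0, x0]
    tr = img[y0, x0 + 1]
    bl = img[y0 + 1, x0]
    br = img[y0 + 1, x0 + 1]
    return (tl * (1 - fy) * (1 - fx) + tr * (1 - fy) * fx
            + bl * fy * (1 - fx) + br * fy * fx)


class _FramePyramid:
    """Cached Gaussian pyramid for one luminance frame."""

    __slots__ = ("levels",)

    def __init__(self, img: np.ndarray, m: int):
        if _kernels.HAVE_NUMBA and img.dtype == np.float32:
            if m > 0 and min(img.shape) // (2 ** (m - 1)) < 4:
                raise ValueError(f"image too small for {m} pyramid levels")
            levels = [img]
            for _ in range(m):
                levels.append(_kernels.pyr_down(levels[-1]))
            self.levels = levels
        else:
            self.levels = gaussian_pyramid(img, m)


def _finalize_flow(prev: _FramePyramid, pts: np.ndarray, g: np.ndarray,
                   lost: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    new_pts = pts + g
    h, w = prev.levels[0].shape
    lost = lost | ((new_pts[:, 0] < 0) | (new_pts[:, 0] > w - 1)
                   | (new_pts[:, 1] < 0) | (new_pts[:, 1] > h - 1))
    return g, lost


def _lk_batch_fast(prev: _FramePyramid, nxt: _FramePyramid, pts: np.ndarray,
                   cfg: FlowConfig) -> tuple[np.ndarray, np.ndarray]:
    """numba path of _lk_batch (identical algorithm, per-point loops)."""
    n_pts = pts.shape[0]
    g = np.zeros((n_pts, 2))
    lost = np.zeros(n_pts, bool)
    r = cfg.window_size // 2
    for lv in range(len(prev.levels) - 1, -1, -1):
        scale = 2.0 ** lv
        _kernels.lk_level(prev.levels[lv], nxt.levels[lv],
                          pts[:, 0] / scale, pts[:, 1] / scale, g, lost,
                          r, cfg.max_iterations, cfg.update_epsilon,
                          cfg.min_eigen_threshold)
        if lv > 0:
            g *= 2.0
    return _finalize_flow(prev, pts, g, lost)


def _lk_batch(prev: _FramePyramid, nxt: _FramePyramid, pts: np.ndarray,
              cfg: FlowConfig) -> tuple[np.ndarray, np.ndarray]:
    """Track points (P, 2 as x, y) from prev to next frame.

    Returns (flow, lost): flow in pixels at full resolution; lost marks
    points whose window was gradient-deficient or left the image.
    """
    pts = np.atleast_2d(np.asarray(pts, float))
    if _kernels.HAVE_NUMBA and prev.levels[0].dtype == np.float32:
        return _lk_batch_fast(prev, nxt, pts, cfg)
    n_pts = pts.shape[0]
    r = cfg.window_size // 2
    offs = np.arange(-r, r + 1, dtype=float)
    offs_pad = np.arange(-r - 1, r + 2, dtype=float)
    g = np.zeros((n_pts, 2))
    lost = np.zeros(n_pts, bool)
    for lv in range(len(prev.levels) - 1, -1, -1):
        scale = 2.0 ** lv
        px = pts[:, 0] / scale
        py = pts[:, 1] / scale
        wy = py[:, None, None] + offs[None, :, None]
        wx = px[:, None, None] + offs[None, None, :]
        lvl = prev.levels[lv]
        # one padded sample gives the template and, since the sampling
        # grid is unit-spaced, its central-difference gradients too
        pad = _bilinear(lvl,
                        py[:, None, None] + offs_pad[None, :, None],
                        px[:, None, None] + offs_pad[None, None, :])
        t_win = pad[:, 1:-1, 1:-1]
        tx = (pad[:, 1:-1, 2:] - pad[:, 1:-1, :-2]) / 2
        ty = (pad[:, 2:, 1:-1] - pad[:, :-2, 1:-1]) / 2
        g11 = (tx * tx).sum(axis=(1, 2))
        g12 = (tx * ty).sum(axis=(1, 2))
        g22 = (ty * ty).sum(axis=(1, 2))
        half_tr = (g11 + g22) / 2
        min_eig = half_tr - np.sqrt(((g11 - g22) / 2) ** 2 + g12 ** 2)
        lost |= min_eig < cfg.min_eigen_threshold
        det = g11 * g22 - g12 * g12
        det = np.where(lost, 1.0, det)  # dummy, masked out below
        d = np.zeros((n_pts, 2))
        active = ~lost
        for _ in range(cfg.max_iterations):
            if not active.any():
                break
            sy = wy + (g[:, 1] + d[:, 1])[:, None, None]
            sx = wx + (g[:, 0] + d[:, 0])[:, None, None]
            n_win = _bilinear(nxt.levels[lv], sy, sx)
            err = n_win - t_win
            b1 = -(tx * err).sum(axis=(1, 2))
            b2 = -(ty * err).sum(axis=(1, 2))
            inc_x = (g22 * b1 - g12 * b2) / det
            inc_y = (g11 * b2 - g12 * b1) / det
            d[active, 0] += inc_x[active]
            d[active, 1] += inc_y[active]
            step = np.hypot(inc_x, inc_y)
            active = active & (step >= cfg.update_epsilon)
        g = g + d
        if lv > 0:
            g *= 2.0
    return _finalize_flow(prev, pts, g, lost)


def lk_flow_at_point(i_prev: np.ndarray, i_next: np.ndarray,
                     point: tuple[float, float] | FeaturePoint,
                     cfg: FlowConfig | None = None
                     ) -> tuple[np.ndarray, bool]:
    """Optical-flow velocity of one point between two luminance frames.

    Returns (v, lost) with v = (vx, vy) in pixels per frame step.  lost is
    True when the window around the point lacks two-directional gradient
    (singular normal equations) or the track leaves the image.
    """
    cfg = cfg or FlowConfig()
    if isinstance(point, FeaturePoint):
        point = (point.x, point.y)
    prev = _FramePyramid(np.asarray(i_prev, float), cfg.pyramid_levels)
    nxt = _FramePyramid(np.asarray(i_next, float), cfg.pyramid_levels)
    flow, lost = _lk_batch(prev, nxt, np.asarray([point]), cfg)
    return flow[0], bool(lost[0])


def track_frames(lum_frames, det: DetectionConfig | None = None,
                 flow: FlowConfig | None = None, fps: float = 60.0,
                 initial_points: list[FeaturePoint] | None = None
                 ) -> ReservoirSeries:
    """Track through an iterable of luminance frames (streaming core).

    Frames are consumed one at a time, so arbitrarily long clips can be
    tracked in constant memory.  See track_clip for the semantics.
    """
    det = det or DetectionConfig()
    flow = flow or FlowConfig()
    frames = iter(lum_frames)
    first = np.asarray(next(frames))
    points = initial_points if initial_points is not None \
        else detect_features(first, det)
    if not points:
        raise ValueError("no feature points detected on the first frame")
    pos = np.array([[p.x, p.y] for p in points], float)
    n_pts = pos.shape[0]
    rows = [pos.ravel().copy()]
    live = np.ones(n_pts, bool)
    live_rows = [live.copy()]
    prev = _FramePyramid(first, flow.pyramid_levels)
    for frame in frames:
        nxt = _FramePyramid(np.asarray(frame), flow.pyramid_levels)
        if live.any():
            flow_vec, lost_now = _lk_batch(prev, nxt, pos[live], flow)
            was_live = np.nonzero(live)[0]
            still = ~lost_now
            pos[was_live[still]] += flow_vec[still]
            live[was_live[lost_now]] = False
        rows.append(pos.ravel().copy())
        live_rows.append(live.copy())
        prev = nxt
    if len(rows) < 2:
        raise ValueError("a clip needs at least 2 frames")
    return ReservoirSeries(np.asarray(rows), np.array([p.id for p in points]),
                           fps=fps, lost_mask=np.asarray(live_rows))


def track_clip(clip: VideoClip,
               det: DetectionConfig | None = None,
               flow: FlowConfig | None = None,
               pool_k: int = 1,
               initial_points: list[FeaturePoint] | None = None
               ) -> ReservoirSeries:
    """Detect corners on the first frame and track them through the clip.

    With pool_k > 1 the RGB frames are max-pooled first (coordinates are
    then in pooled-pixel units).  Lost points keep their last valid
    coordinates and are flagged in lost_mask, so X stays rectangular.
    ``initial_points`` bypasses detection, e.g. to reuse one detection
    across clips that share a first frame.
    """
    if pool_k > 1:
        clip = pool_clip(clip, pool_k)
    lum = clip_to_luminance(clip)
    return track_frames(iter(lum), det, flow, fps=clip.fps,
                        initial_points=initial_points)
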