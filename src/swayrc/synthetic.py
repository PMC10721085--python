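"""Synthetic plant-sway benchmark generator.

A desk-scale stand-in for a foliage plant filmed under a directional fan:
each "leaf" is a damped 2-D oscillator node pulled toward its rest
position, coupled to its neighbours, and driven by a wind force whose mean
direction and magnitude encode the class (direction x speed level).  Wind
speed also adds a small downward "droop" component (drag flattening the
leaves) and gusty i.i.d. Gaussian force noise whose scale grows with
speed.  Nodes are rendered as corner-rich textured blobs so the Shi-Tomasi
/ Lucas-Kanade front end has something to grab.

Each class is simulated and rendered as its own clip that starts from the
identical rest configuration (the recording of a steady-fan condition):
forcing ramps up over ramp_frames and the first settle_frames are excluded
from the labelled series, so labelled steps sample the statistically
steady response.  Because every clip shares frame 0, one corner detection
aligns the tracked columns across classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .video import VideoClip, LUMA_WEIGHTS, rgb_to_luminance
from .tracking import (DetectionConfig, FlowConfig, ReservoirSeries,
                       detect_features, track_frames)
from .readout import LabelSeries
from . import _kernels


@dataclass(frozen=True)
class WindClass:
    """One wind condition: direction in degrees (0 = +x, measured toward
    the deflection direction, y increasing downward) and fan speed level
    in {1, 4, 7}."""

    class_id: int
    direction: float
    speed_level: int


def wind_classes(task: str) -> list[WindClass]:
    """Class tables for the two benchmark tasks.

    six_class: two opposite directions (left = 180 deg, right = 0 deg) x
    three speeds, numbered class = 2 * speed_index + direction_index so
    classes 0, 2, 4 are left with low/middle/strong wind and 1, 3, 5 are
    right.  twenty_four_class: eight directions at 45-degree intervals x
    three speeds, numbered class = direction_index * 3 + speed_index.
    """
    speeds = (1, 4, 7)
    if task == "six_class":
        dirs = (180.0, 0.0)  # left, right
        return [WindClass(2 * si + di, d, s)
                for si, s in enumerate(speeds)
                for di, d in enumerate(dirs)]
    if task == "twenty_four_class":
        dirs = tuple(45.0 * i for i in range(8))
        return [WindClass(di * 3 + si, d, s)
                for di, d in enumerate(dirs)
                for si, s in enumerate(speeds)]
    raise ValueError(f"unknown task {task!r}")


@dataclass
class SwayConfig:
    """Full parameterization of the synthetic plant and its rendering.

    Dynamical constants are in per-frame units (the simulation step is one
    frame).  forcing_gain and droop relate fan speed level to force:
    equilibrium deflection is forcing_gain * level / stiffness px along
    the wind direction (2.5 px per level with the defaults), plus
    droop_fraction of that downward.  turbulence_sd * level is the
    standard deviation of the i.i.d. Gaussian force noise.
    """

    n_nodes: int = 24
    frame_shape: tuple[int, int] = (544, 640)  # (H, W)
    grid: tuple[int, int] = (4, 6)             # nodes: rows x cols
    node_spacing: float = 70.0
    stiffness: float = 0.02      # 1/frame^2
    damping: float = 0.4         # 1/frame
    coupling: float = 0.01       # 1/frame^2, chain Laplacian
    forcing_gain: float = 1.15   # px/frame^2 at full saturation
    sat_level: float = 1.5       # speed scale of deflection-magnitude saturation
    align_level: float = 6.0     # speed scale of hinge-to-wind realignment
    sat_spread: float = 0.8      # lognormal spread of per-leaf saturations
    gain_spread: float = 0.2     # lognormal spread of per-leaf drag gain
    twist_max_deg: float = 30.0  # sd of per-leaf load-induced reorientation
    tuck_spread: float = 0.5     # sd of per-leaf high-load tuck (curl) factor
    tuck_level: float = 5.0      # speed scale where curling sets in
    droop_fraction: float = 0.3  # vertical force as fraction of wind force
    droop_spread: float = 1.0    # per-leaf spread of the vertical response
    turbulence_sd: float = 0.02  # px/frame^2 per speed level
    heterogeneity_sd: float = 0.1
    fps: float = 60.0
    duration_per_class: int = 720
    settle_frames: int = 150
    ramp_frames: int = 90
    seed: int = 0
    blob_radius: int = 9
    texture_contrast: float = 110.0
    background_level: float = 128.0  # keeps background+texture inside 0..255

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.damping <= 0:
            raise ValueError("damping must be positive (bounded sway)")
        if self.duration_per_class < 2:
            raise ValueError("duration_per_class must be >= 2")
        if self.grid[0] * self.grid[1] < self.n_nodes:
            raise ValueError("grid too small for n_nodes")

    def rest_positions(self) -> np.ndarray:
        """(n_nodes, 2) rest coordinates (x, y), grid centred in frame."""
        rows, cols = self.grid
        h, w = self.frame_shape
        x0 = (w - (cols - 1) * self.node_spacing) / 2
        y0 = (h - (rows - 1) * self.node_spacing) / 2
        pos = [(x0 + c * self.node_spacing, y0 + r * self.node_spacing)
               for r in range(rows) for c in range(cols)]
        return np.asarray(pos[: self.n_nodes], float)


def _plant_rng(cfg: SwayConfig) -> np.random.Generator:
    """RNG for plant-intrinsic randomness (textures, heterogeneity):
    shared across classes so every clip shows the same plant."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))


def plant_params(cfg: SwayConfig) -> dict:
    """Per-node plant-intrinsic parameters, fixed across wind classes.

    Each leaf node has its own stiffness, drag gain, saturation speed and
    load-induced reorientation ("twist") angle.  The saturating,
    twisting drag law makes the mean deflection a *nonlinear*, leaf-
    specific function of wind speed — real foliage streamlines and
    reorients under load — and that node-to-node nonlinearity is what
    turns the plant into a useful reservoir: it spreads the class
    information over many independent directions of the state space
    instead of a single common sway mode.
    """
    rng = _plant_rng(cfg)
    z_k = rng.standard_normal(cfg.n_nodes)
    z_g = rng.standard_normal(cfg.n_nodes)
    z_s = rng.standard_normal(cfg.n_nodes)
    z_t = rng.standard_normal(cfg.n_nodes)
    z_c = rng.standard_normal(cfg.n_nodes)
    z_d = rng.standard_normal(cfg.n_nodes)
    return {
        # vertical response: mostly droop (downward), some leaves lift
        "droop_sign": 1.0 + np.clip(cfg.droop_spread * z_d, -2.0, 1.0),
        "stiffness": cfg.stiffness
        * np.exp(np.clip(cfg.heterogeneity_sd * z_k, -0.5, 0.5)),
        "gain": np.exp(np.clip(cfg.gain_spread * z_g, -0.4, 0.4)),
        "sat_level": cfg.sat_level * np.exp(np.clip(cfg.sat_spread * z_s,
                                                    -1.2, 1.2)),
        "align_level": cfg.align_level
        * np.exp(np.clip(cfg.sat_spread * rng.standard_normal(cfg.n_nodes),
                         -1.2, 1.2)),
        "twist": np.deg2rad(cfg.twist_max_deg) * np.clip(z_t, -2.0, 2.0),
        "tuck": np.clip(np.abs(cfg.tuck_spread * z_c), 0.0, 0.8),
        "tuck_level": cfg.tuck_level
        * np.exp(np.clip(0.4 * rng.standard_normal(cfg.n_nodes), -0.8, 0.8)),
        "hinge": rng.uniform(0.0, 2 * np.pi, cfg.n_nodes),
    }


def steady_deflection(cfg: SwayConfig, wc: WindClass,
                      plant: dict | None = None) -> np.ndarray:
    """Equilibrium deflection (n_nodes, 2) of each node for a wind class.

    Each leaf responds with a saturating magnitude
    D_i(s) = (forcing_gain / stiffness) * gain_i * tanh(s / sat_i) *
    (1 - tuck_i * load^2) (streamlining, then curling at high load).  At
    low load the leaf swings along its own petiole hinge axis (the wind
    force projected onto the hinge); with increasing load it aligns with
    the wind direction, rotated by a leaf-specific twist.  A downward
    droop of droop_fraction times the magnitude is added.  The resulting
    mean state is a nonlinear, leaf-specific function of both direction
    and speed — the property that makes the plant a useful reservoir.
    """
    plant = plant or plant_params(cfg)
    s = wc.speed_level
    load = np.tanh(s / plant["sat_level"])  # magnitude load, saturates early
    curl = plant["tuck"] * np.tanh(s / plant["tuck_level"]) ** 2
    mag = (cfg.forcing_gain / cfg.stiffness) * plant["gain"] * load \
        * (1.0 - curl)
    # realignment progresses over the whole speed range
    align = np.tanh(s / plant["align_level"]) ** 2
    phi = np.deg2rad(wc.direction) + plant["twist"] * align
    wind_dir = np.column_stack([np.cos(phi), np.sin(phi)])
    hinge = np.column_stack([np.cos(plant["hinge"]), np.sin(plant["hinge"])])
    proj = (hinge * wind_dir).sum(axis=1)  # wind component along the hinge
    direction = ((1.0 - align)[:, None] * proj[:, None] * hinge
                 + align[:, None] * wind_dir)
    defl = mag[:, None] * direction
    defl[:, 1] += cfg.droop_fraction * mag * plant["droop_sign"]
    return defl


def simulate_segment(cfg: SwayConfig, wc: WindClass) -> np.ndarray:
    """Node positions for one wind-condition clip.

    Returns (settle_frames + duration_per_class, n_nodes, 2) absolute
    pixel positions; frame 0 is exactly the rest configuration.  Raises
    if the parameterization diverges.
    """
    total = cfg.settle_frames + cfg.duration_per_class
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, wc.class_id]))
    plant = plant_params(cfg)
    k = plant["stiffness"][:, None]
    rest = cfg.rest_positions()
    # steady wind force = stiffness * equilibrium deflection
    steady = k * steady_deflection(cfg, wc, plant)
    sigma = cfg.turbulence_sd * wc.speed_level
    noise = sigma * rng.standard_normal((total - 1, cfg.n_nodes, 2))
    if cfg.ramp_frames > 0:
        ramp = np.minimum(np.arange(1, total) / cfg.ramp_frames, 1.0)
    else:
        ramp = np.ones(total - 1)
    bound = float(np.hypot(*cfg.frame_shape))
    if _kernels.HAVE_NUMBA:
        out = _kernels.sway_steps(rest, k, steady, noise, cfg.damping,
                                  cfg.coupling, ramp, bound)
        if np.isnan(out[0, 0, 0]):
            raise ValueError("sway dynamics diverged; reduce stiffness/"
                             "forcing or increase damping")
        return out
    d = np.zeros((cfg.n_nodes, 2))
    v = np.zeros((cfg.n_nodes, 2))
    out = np.empty((total, cfg.n_nodes, 2))
    out[0] = rest
    for t in range(1, total):
        force = ramp[t - 1] * (steady + noise[t - 1])
        lap = np.zeros_like(d)
        if cfg.n_nodes > 1:  # chain coupling with free ends
            lap[1:] += d[:-1] - d[1:]
            lap[:-1] += d[1:] - d[:-1]
        a = -k * d - cfg.damping * v + cfg.coupling * lap + force
        v = v + a
        d = d + v
        if np.abs(d).max() > bound:
            raise ValueError("sway dynamics diverged; reduce stiffness/"
                             "forcing or increase damping")
        out[t] = rest + d
    return out


def _positions_to_series(pos: np.ndarray, fps: float) -> ReservoirSeries:
    n, p, _ = pos.shape
    return ReservoirSeries(pos.reshape(n, 2 * p), np.arange(p), fps=fps)


def simulate_sway(cfg: SwayConfig, classes: list[WindClass]
                  ) -> tuple[ReservoirSeries, LabelSeries]:
    """Concatenated labelled node trajectories for the given classes.

    Each class contributes duration_per_class steady-state steps (the
    settle window is simulated but not labelled).
    """
    if not classes:
        raise ValueError("need at least one wind class")
    blocks, labels = [], []
    for wc in classes:
        pos = simulate_segment(cfg, wc)[cfg.settle_frames:]
        blocks.append(pos)
        labels.append(np.full(pos.shape[0], wc.class_id))
    pos = np.concatenate(blocks)
    n_classes = max(wc.class_id for wc in classes) + 1
    table = {wc.class_id: (wc.direction, wc.speed_level) for wc in classes}
    return (_positions_to_series(pos, cfg.fps),
            LabelSeries(np.concatenate(labels), n_classes, table))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _node_textures(cfg: SwayConfig) -> tuple[np.ndarray, np.ndarray]:
    """(textures, tints): per-node luminance patches and RGB tint weights.

    Each patch is smoothed zero-mean noise under a raised-cosine radial
    window, so it is corner-rich in its interior and blends to zero at
    the rim.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    s = 2 * cfg.blob_radius + 1
    yy, xx = np.mgrid[:s, :s] - cfg.blob_radius
    r = np.hypot(yy, xx) / (cfg.blob_radius + 0.5)
    window = np.where(r < 1.0, np.cos(np.pi * r / 2) ** 2, 0.0)
    textures = np.empty((cfg.n_nodes, s, s))
    for i in range(cfg.n_nodes):
        noise = ndimage.gaussian_filter(rng.standard_normal((s, s)), 1.0)
        noise /= max(np.abs(noise).max(), 1e-9)
        textures[i] = cfg.texture_contrast * noise * window
    # greenish foliage tints, slightly varied per node
    base = np.array([0.45, 0.9, 0.5])
    tints = np.clip(base + 0.1 * rng.standard_normal((cfg.n_nodes, 3)), 0.1, 1.0)
    return textures, tints


def _render_frame(pos_t: np.ndarray, textures: np.ndarray, tints: np.ndarray,
                  cfg: SwayConfig, frame_index: int = 0) -> np.ndarray:
    """One H x W x 3 uint8 frame with blobs at pos_t (n_nodes, 2)."""
    h, w = cfg.frame_shape
    rad = cfg.blob_radius
    rgb = np.full((h, w, 3), cfg.background_level, dtype=np.float32)
    for i in range(pos_t.shape[0]):
        x, y = pos_t[i]
        ix, iy = int(np.floor(x)), int(np.floor(y))
        fx, fy = x - ix, y - iy
        top, left = iy - rad, ix - rad
        s = 2 * rad + 2  # patch side + 1 for the fractional spill
        if top < 0 or left < 0 or top + s > h or left + s > w:
            raise ValueError(f"node {i} out of frame bounds at frame "
                             f"{frame_index} (position {x:.1f}, {y:.1f})")
        tex = textures[i]
        shifted = np.zeros((s, s))
        shifted[:-1, :-1] += (1 - fy) * (1 - fx) * tex
        shifted[:-1, 1:] += (1 - fy) * fx * tex
        shifted[1:, :-1] += fy * (1 - fx) * tex
        shifted[1:, 1:] += fy * fx * tex
        rgb[top: top + s, left: left + s] += shifted[..., None] * tints[i]
    return np.clip(rgb, 0, 255).astype(np.uint8)


def render_video(series: ReservoirSeries, cfg: SwayConfig) -> VideoClip:
    """Render node trajectories as a textured-blob video clip.

    The series columns must be node coordinates (x_i, y_i interleaved).
    Blobs are placed with subpixel (bilinear) accuracy.  Raises when a
    node's blob would leave the frame, naming the node and frame.
    """
    n = series.n_steps
    n_nodes = series.n_units // 2
    textures, tints = _node_textures(cfg)
    if n_nodes > textures.shape[0]:
        raise ValueError("series has more nodes than cfg.n_nodes")
    pos = series.X.reshape(n, n_nodes, 2)
    frames = np.stack([_render_frame(pos[t], textures, tints, cfg, t)
                       for t in range(n)])
    return VideoClip(frames, fps=cfg.fps)


def _check_render_bounds(pos: np.ndarray, cfg: SwayConfig) -> None:
    """Raise early if any blob would leave the frame."""
    h, w = cfg.frame_shape
    rad = cfg.blob_radius
    lo = pos.min(axis=(0, 1))
    hi = pos.max(axis=(0, 1))
    if (np.floor(lo) < rad).any() or hi[0] + rad + 2 > w or hi[1] + rad + 2 > h:
        t, i = np.unravel_index(
            np.argmax(np.abs(pos - pos.mean((0, 1))).max(-1)), pos.shape[:2])
        raise ValueError(
            f"sway exceeds frame bounds (e.g. node {i} at frame {t}); "
            "reduce forcing_gain or enlarge frame_shape")


def _render_luminance(pos_t: np.ndarray, textures: np.ndarray,
                      tints: np.ndarray, cfg: SwayConfig,
                      frame_index: int = 0) -> np.ndarray:
    """Luminance of the rendered frame (fast path when numba is present).

    Identical (to uint8 quantization) to
    rgb_to_luminance(_render_frame(...)); bounds must be pre-checked.
    """
    if not _kernels.HAVE_NUMBA:
        return rgb_to_luminance(
            _render_frame(pos_t, textures, tints, cfg, frame_index),
            dtype=np.float32)
    h, w = cfg.frame_shape
    xs = np.ascontiguousarray(pos_t[:, 0])
    ys = np.ascontiguousarray(pos_t[:, 1])
    wts = np.asarray(LUMA_WEIGHTS, np.float32)
    bgq = np.uint8(np.clip(cfg.background_level, 0, 255))
    field = np.zeros((h, w, 3), np.float32)
    _kernels.paint_blobs(field, textures.astype(np.float32, copy=False),
                         tints.astype(np.float32, copy=False), xs, ys)
    rgb = np.full((h, w, 3), bgq, np.uint8)
    lum_bg = np.float32(bgq) * wts[0] + np.float32(bgq) * wts[1] \
        + np.float32(bgq) * wts[2]
    lum = np.full((h, w), lum_bg, np.float32)
    _kernels.quantize_blobs(field, rgb, lum, xs, ys, cfg.blob_radius,
                            np.float32(cfg.background_level), wts)
    return lum


# ---------------------------------------------------------------------------
# end-to-end benchmark
# ---------------------------------------------------------------------------


@dataclass
class Benchmark:
    """A tracked, labelled, chronologically split synthetic benchmark.

    X holds one row per labelled step, classes in block order; train_idx /
    test_idx are the per-class chronological 70/30 split.  segment_starts_*
    give the row offsets (within the train/test submatrices) where a new
    recording begins — score smoothing must reset there.
    """

    X: np.ndarray
    labels: LabelSeries
    train_idx: np.ndarray
    test_idx: np.ndarray
    segment_starts_train: np.ndarray
    segment_starts_test: np.ndarray
    fps: float
    manifest: dict

    @property
    def X_train(self) -> np.ndarray:
        return self.X[self.train_idx]

    @property
    def X_test(self) -> np.ndarray:
        return self.X[self.test_idx]

    @property
    def y_train(self) -> np.ndarray:
        return self.labels.labels[self.train_idx]

    @property
    def y_test(self) -> np.ndarray:
        return self.labels.labels[self.test_idx]


def default_config(task: str) -> SwayConfig:
    """Benchmark recording protocol for a task.

    The six-class study records each condition for 48 s (2880 frames at
    60 FPS); the 24-class study spreads the session over four times as
    many conditions, so each is recorded for 12 s (720 frames).
    """
    durations = {"six_class": 2880, "twenty_four_class": 720}
    if task not in durations:
        raise ValueError(f"unknown task {task!r}")
    return SwayConfig(duration_per_class=durations[task])


def make_benchmark(task: str = "six_class",
                   cfg: SwayConfig | None = None,
                   seed: int | None = None,
                   mode: str = "video",
                   train_fraction: float = 0.7,
                   det: DetectionConfig | None = None,
                   flow: FlowConfig | None = None) -> Benchmark:
    """Build a six- or 24-class wind benchmark.

    mode="video" runs the full harvest: simulate each class clip, render
    it, track blobs with Shi-Tomasi + pyramidal LK, and collect the
    tracked coordinates.  mode="series" skips rendering/tracking and uses
    the simulated node coordinates directly (fast, for readout-level
    work).  The split is chronological per class (first 70% of each
    recording trains, the last 30% tests).
    """
    cfg = cfg or default_config(task)
    if seed is not None:
        cfg = SwayConfig(**{**asdict(cfg), "seed": seed})
    if mode not in ("video", "series"):
        raise ValueError(f"unknown mode {mode!r}")
    classes = wind_classes(task)
    det = det or DetectionConfig()
    flow = flow or FlowConfig()
    blocks: list[np.ndarray] = []
    initial_points = None
    n_points = None
    if mode == "video":
        textures, tints = _node_textures(cfg)
        textures = textures.astype(np.float32)
        tints = tints.astype(np.float32)
    for wc in classes:
        pos = simulate_segment(cfg, wc)
        if mode == "series":
            x_cls = pos[cfg.settle_frames:].reshape(
                pos.shape[0] - cfg.settle_frames, -1)
        else:
            _check_render_bounds(pos, cfg)
            if initial_points is None:
                first = rgb_to_luminance(
                    _render_frame(pos[0], textures, tints, cfg, 0))
                initial_points = detect_features(first, det)
                if not initial_points:
                    raise ValueError("no feature points detected on the "
                                     "rendered rest frame")
                n_points = len(initial_points)
            lum_frames = (_render_luminance(pos[t], textures, tints, cfg, t)
                          for t in range(pos.shape[0]))
            tracked = track_frames(lum_frames, det, flow, fps=cfg.fps,
                                   initial_points=initial_points)
            x_cls = tracked.X[cfg.settle_frames:]
        blocks.append(x_cls)
    X = np.concatenate(blocks)
    n_classes = max(wc.class_id for wc in classes) + 1
    table = {wc.class_id: (wc.direction, wc.speed_level) for wc in classes}
    labels = LabelSeries(
        np.concatenate([np.full(b.shape[0], wc.class_id)
                        for b, wc in zip(blocks, classes)]),
        n_classes, table)
    train_idx, test_idx, seg_tr, seg_te = [], [], [], []
    offset = 0
    for b in blocks:
        n_b = b.shape[0]
        n_tr = int(round(train_fraction * n_b))
        seg_tr.append(len(train_idx))
        seg_te.append(len(test_idx))
        train_idx.extend(range(offset, offset + n_tr))
        test_idx.extend(range(offset + n_tr, offset + n_b))
        offset += n_b
    manifest = {"task": task, "mode": mode, "config": asdict(cfg),
                "train_fraction": train_fraction,
                "n_classes": n_classes, "n_units": X.shape[1],
                "n_feature_points": n_points if mode == "video"
                else cfg.n_nodes,
                "class_table": {c.class_id: [c.direction, c.speed_level]
                                for c in classes}}
    manifest["config"]["frame_shape"] = list(cfg.frame_shape)
    manifest["config"]["grid"] = list(cfg.grid)
    return Benchmark(X, labels, np.asarray(train_idx), np.asarray(test_idx),
                     np.asarray(seg_tr), np.asarray(seg_te), cfg.fps, manifest)
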