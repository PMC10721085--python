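"""Video containers and frame preprocessing.

The tracking pipeline works on luminance images at reduced resolution:
raw RGB frames are first shrunk with a k x k max-pooling filter (applied
per color channel), then converted to a single luminance channel.  Max
pooling is preferred over mean pooling here because it preserves small
high-contrast structures (leaf edges, specular highlights) that corner
detection relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from skimage.measure import block_reduce

#: Rec.601 luma coefficients (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class VideoClip:
    """An ordered stack of equally sized RGB frames.

    Parameters
    ----------
    frames
        Array of shape (n_frames, H, W, 3), values in [0, 255].
    fps
        Frame rate in frames per second.
    """

    frames: np.ndarray
    fps: float = 60.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must be (n, H, W, 3), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a clip needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of each frame."""
        return self.frames.shape[1:3]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)


def rgb_to_luminance(frame: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Convert an H x W x 3 RGB frame to a scalar luminance field.

    Uses the Rec.601 luma weights (0.299, 0.587, 0.114); for equal
    channels the input value is returned unchanged (the weights sum
    to 1).  dtype selects the working precision (float32 is enough for
    tracking and halves the memory traffic).
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 RGB frame, got shape {frame.shape}")
    frame = frame.astype(dtype, copy=False)
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite values")
    w = np.asarray(LUMA_WEIGHTS, dtype=dtype)
    return frame @ w


def max_pool(frame: np.ndarray, k: int = 3) -> np.ndarray:
    """Reduce a raster with k x k max pooling.

    Each output pixel is the maximum over a k x k block of the input;
    output dimensions are ceil(H/k) x ceil(W/k) (ragged edge blocks are
    simply smaller).  A trailing channel axis, if present, is pooled
    per channel.  With the default k=3 a 1920x1080 frame becomes 640x360.
    """
    frame = np.asarray(frame)
    if not isinstance(k, (int, np.integer)) or k <= 0:
        raise ValueError(f"pool size must be a positive integer, got {k}")
    if frame.size == 0:
        raise ValueError("frame is empty")
    if k == 1:
        return frame.copy()
    if frame.ndim == 2:
        block = (k, k)
    elif frame.ndim == 3:
        block = (k, k, 1)
    else:
        raise ValueError(f"expected 2-D or 3-D raster, got shape {frame.shape}")
    # -inf padding keeps ragged edge blocks exact for any dtype/sign.
    out = block_reduce(frame.astype(np.float64), block, np.max, cval=-np.inf)
    if np.issubdtype(frame.dtype, np.integer):
        return out.astype(frame.dtype)
    return out.astype(frame.dtype, copy=False)


def pool_clip(clip: VideoClip, k: int = 3) -> VideoClip:
    """Max-pool every frame of a clip (per RGB channel)."""
    if k == 1:
        return clip
    pooled = np.stack([max_pool(f, k) for f in clip.frames])
    return VideoClip(pooled, fps=clip.fps)


def clip_to_luminance(clip: VideoClip) -> np.ndarray:
    """Stack of luminance frames, shape (n_frames, H, W), float64."""
    return np.stack([rgb_to_luminance(f) for f in clip.frames])


# ---------------------------------------------------------------------------
# File I/O.  Canonical on-disk formats are multi-page TIFF (portable, no
# extra codecs needed) and NumPy .npz; other containers (MP4/AVI) are
# delegated to imageio and work wherever an ffmpeg plugin is installed.
# ---------------------------------------------------------------------------


def read_video(path: str | Path, fps: float | None = None) -> VideoClip:
    """Read a clip from disk.

    ``.npz`` archives (keys ``frames``, ``fps``) and multi-page TIFF are
    read natively; any other extension is handed to imageio, which may
    require an ffmpeg plugin for MP4/AVI.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        with np.load(path) as data:
            return VideoClip(data["frames"], fps=float(data["fps"]))
    import imageio.v3 as iio

    frames = np.asarray(iio.imread(path))
    if frames.ndim == 3:  # grayscale stack -> replicate to RGB
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if fps is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            fps = float(json.loads(sidecar.read_text()).get("fps", 60.0))
        else:
            fps = 60.0
    return VideoClip(frames, fps=fps)


def write_video(clip: VideoClip, path: str | Path) -> Path:
    """Write a clip to disk (format chosen by extension, see read_video)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    frames = np.clip(clip.frames, 0, 255).astype(np.uint8)
    if suffix == ".npz":
        np.savez_compressed(path, frames=frames, fps=clip.fps)
        return path
    import imageio.v3 as iio

    iio.imwrite(path, frames)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"fps": clip.fps, "n_frames": clip.n_frames,
                                   "shape": list(clip.shape)}))
    return path
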