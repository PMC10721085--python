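"""Shared fixtures.

The two full-pipeline benchmarks (simulate -> render -> track) are
session-scoped because they are the expensive part of the suite; all
round-trip and readout-level tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import swayrc as srv
from swayrc.synthetic import SwayConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_cfg() -> SwayConfig:
    """Short recordings for experiment-level tests (series mode)."""
    return SwayConfig(duration_per_class=360, settle_frames=100, seed=7)


@pytest.fixture(scope="session")
def series_bench(fast_cfg):
    """Small six-class benchmark from simulated node positions."""
    return srv.make_benchmark("six_class", fast_cfg, mode="series")


@pytest.fixture(scope="session")
def video_bench_six():
    """Full default six-class video round trip (the headline benchmark)."""
    return srv.make_benchmark("six_class", seed=1, mode="video")


@pytest.fixture(scope="session")
def video_bench_24():
    """Full default 24-class video round trip."""
    return srv.make_benchmark("twenty_four_class", seed=1, mode="video")


@pytest.fixture()
def textured_image(rng):
    """Smooth random luminance field, rich in corners everywhere."""
    img = ndimage.gaussian_filter(rng.standard_normal((96, 128)), 1.5)
    return 128.0 + 400.0 * img


def make_blob_image(centers, shape=(120, 160), radius=4, value=200.0):
    """Isolated square bumps at given (x, y) centers on a dark field."""
    img = np.zeros(shape)
    for cx, cy in centers:
        img[cy - radius: cy + radius + 1, cx - radius: cx + radius + 1] = value
    return img
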