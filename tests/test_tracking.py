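"""Corner detection and pyramidal Lucas-Kanade tracking."""

import numpy as np
import pytest
from scipy import ndimage

from swayrc import (DetectionConfig, FlowConfig, VideoClip, corner_response,
                    corner_response_map, detect_features, gaussian_pyramid,
                    lk_flow_at_point, structure_tensor, track_clip)
from swayrc.tracking import central_gradients
from swayrc import _kernels

from conftest import make_blob_image


def structure_tensor_oracle(img, center, patch):
    """Naive double-loop accumulation of the gradient products."""
    ix, iy = central_gradients(img)
    cx, cy = int(center[0]), int(center[1])
    r = patch // 2
    a = b = c = 0.0
    for y in range(cy - r, cy + r + 1):
        for x in range(cx - r, cx + r + 1):
            a += ix[y, x] ** 2
            b += ix[y, x] * iy[y, x]
            c += iy[y, x] ** 2
    return np.array([[a, b], [b, c]])


def min_eig_oracle(A):
    """Smaller root of the characteristic polynomial, solved directly."""
    tr, det = A[0, 0] + A[1, 1], A[0, 0] * A[1, 1] - A[0, 1] ** 2
    return (tr - np.sqrt(tr * tr - 4 * det)) / 2


def ssd_search(prev, nxt, center, window, max_shift):
    """Brute-force integer-shift SSD minimization oracle."""
    cx, cy = center
    r = window // 2
    ref = prev[cy - r: cy + r + 1, cx - r: cx + r + 1]
    best, best_ssd = (0, 0), np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            cand = nxt[cy + dy - r: cy + dy + r + 1,
                       cx + dx - r: cx + dx + r + 1]
            ssd = float(((cand - ref) ** 2).sum())
            if ssd < best_ssd:
                best, best_ssd = (dx, dy), ssd
    return best


class TestStructureTensor:
    def test_constant_image_zero(self):
        A = structure_tensor(np.full((20, 20), 9.0), (10, 10), 7)
        assert np.allclose(A, 0.0)

    def test_vertical_edge_rank_one(self):
        img = np.tile(np.arange(20.0), (20, 1))  # gradient along x only
        A = structure_tensor(img, (10, 10), 7)
        assert A[1, 1] == 0.0 and A[0, 1] == 0.0 and A[0, 0] > 0

    def test_matches_naive_loop(self, rng):
        img = rng.standard_normal((15, 15))
        A = structure_tensor(img, (7, 7), 7)
        assert np.allclose(A, structure_tensor_oracle(img, (7, 7), 7))

    def test_patch_outside_bounds(self):
        with pytest.raises(ValueError):
            structure_tensor(np.zeros((10, 10)), (1, 1), 7)


class TestCornerResponse:
    def test_zero_matrix(self):
        assert corner_response(np.zeros((2, 2))) == 0.0

    def test_diagonal_eigenvalues(self):
        assert corner_response(np.diag([5.0, 2.0])) == pytest.approx(2.0)

    def test_random_psd_matches_quadratic_formula(self, rng):
        for _ in range(20):
            m = rng.standard_normal((2, 2))
            A = m @ m.T
            assert corner_response(A) == pytest.approx(min_eig_oracle(A),
                                                       abs=1e-9)

    def test_harris_mode(self):
        A = np.diag([5.0, 2.0])
        expected = 10.0 - 0.04 * 49.0
        assert corner_response(A, "harris", 0.04) == pytest.approx(expected)


class TestDetection:
    def test_blank_image_empty(self):
        assert detect_features(np.full((50, 50), 3.0)) == []

    def test_close_pair_keeps_stronger(self):
        # two point features 10 px apart; the weaker must be suppressed
        img = np.zeros((90, 90))
        img[40, 40] = 200.0
        img[40, 50] = 100.0
        pts = detect_features(img, DetectionConfig(min_distance=20))
        assert pts  # the strong corner is found
        assert all(np.hypot(p.x - 40, p.y - 40) <= 3 for p in pts)
        assert not any(np.hypot(p.x - 50, p.y - 40) <= 3 for p in pts)

    def test_isolated_blobs_one_point_each(self):
        centers = [(30, 30), (80, 30), (130, 30), (30, 80), (80, 80)]
        img = make_blob_image(centers)
        pts = detect_features(img, DetectionConfig(min_distance=20))
        assert len(pts) == len(centers)
        for cx, cy in centers:
            assert min((p.x - cx) ** 2 + (p.y - cy) ** 2 for p in pts) <= 64

    def test_min_distance_exhaustive(self, textured_image):
        cfg = DetectionConfig(min_distance=11.0)
        pts = detect_features(textured_image, cfg)
        assert len(pts) >= 2
        for i, p in enumerate(pts):
            for q in pts[i + 1:]:
                assert np.hypot(p.x - q.x, p.y - q.y) >= 11.0

    def test_affine_intensity_invariance(self, textured_image):
        base = detect_features(textured_image)
        scaled = detect_features(3.0 * textured_image + 40.0)
        assert [(p.x, p.y) for p in base] == [(p.x, p.y) for p in scaled]

    def test_deterministic_ordering(self, textured_image):
        a = detect_features(textured_image)
        b = detect_features(textured_image)
        assert [(p.x, p.y, p.response) for p in a] == \
            [(p.x, p.y, p.response) for p in b]


class TestPyramid:
    def test_zero_levels(self, textured_image):
        levels = gaussian_pyramid(textured_image, 0)
        assert len(levels) == 1 and levels[0] is not textured_image or \
            np.allclose(levels[0], textured_image)

    def test_quarter_area_per_level(self):
        img = np.zeros((360, 640))
        levels = gaussian_pyramid(img, 3)
        assert [lv.shape for lv in levels] == [(360, 640), (180, 320),
                                              (90, 160), (45, 80)]

    def test_constant_preserved(self):
        levels = gaussian_pyramid(np.full((64, 64), 5.0), 3)
        for lv in levels:
            assert np.allclose(lv, 5.0)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            gaussian_pyramid(np.zeros((4, 4)), 3)


class TestLucasKanade:
    def test_static_frames_zero_flow(self, textured_image):
        v, lost = lk_flow_at_point(textured_image, textured_image, (60, 50),
                                   FlowConfig(pyramid_levels=2))
        assert not lost
        assert np.allclose(v, 0.0, atol=1e-3)

    def test_unit_shift_recovered(self, textured_image):
        nxt = np.roll(textured_image, 1, axis=1)  # shift +1 px in x
        v, lost = lk_flow_at_point(textured_image, nxt, (64, 48),
                                   FlowConfig(pyramid_levels=2))
        assert not lost
        assert abs(v[0] - 1.0) < 0.05 and abs(v[1]) < 0.05

    def test_featureless_window_lost(self):
        flat = np.full((64, 64), 100.0)
        _, lost = lk_flow_at_point(flat, flat, (32, 32),
                                   FlowConfig(pyramid_levels=1))
        assert lost

    def test_agrees_with_ssd_search_on_integer_shifts(self, textured_image):
        cfg = FlowConfig(pyramid_levels=2)
        for shift in ((1, 0), (0, 2), (2, 1), (-2, 1)):
            nxt = np.roll(np.roll(textured_image, shift[1], axis=0),
                          shift[0], axis=1)
            center = (60, 44)
            oracle = ssd_search(textured_image, nxt, center, 15, 4)
            assert oracle == shift  # the SSD oracle finds the true shift
            v, lost = lk_flow_at_point(textured_image, nxt, center, cfg)
            assert not lost
            assert np.allclose(v, shift, atol=0.2)

    def test_large_shift_needs_pyramid(self, rng):
        img = 128 + 300 * ndimage.gaussian_filter(
            rng.standard_normal((128, 192)), 2.5)
        nxt = np.roll(img, 6, axis=1)
        centers = [(x, y) for x in range(40, 160, 12)
                   for y in range(40, 96, 12)]
        cfg3 = FlowConfig(pyramid_levels=3)
        good = 0
        for c in centers:
            v, lost = lk_flow_at_point(img, nxt, c, cfg3)
            if not lost and np.allclose(v, (6, 0), atol=0.2):
                good += 1
        assert good >= 0.95 * len(centers)

    def test_subpixel_translation_within_tolerance(self, rng):
        # render a blob at x and x+0.5 with bilinear subpixel placement
        from swayrc.synthetic import (_render_frame, _node_textures,
                                      SwayConfig)
        cfg = SwayConfig(n_nodes=1, grid=(1, 1))
        tex, tints = _node_textures(cfg)
        f0 = _render_frame(np.array([[80.0, 60.0]]), tex, tints, cfg)
        f1 = _render_frame(np.array([[80.5, 60.0]]), tex, tints, cfg)
        from swayrc import rgb_to_luminance
        v, lost = lk_flow_at_point(rgb_to_luminance(f0), rgb_to_luminance(f1),
                                   (80, 60), FlowConfig(pyramid_levels=1))
        assert not lost
        assert np.allclose(v, (0.5, 0.0), atol=0.1)


class TestTrackClip:
    @staticmethod
    def _blob_clip(velocity, n_frames=30):
        from swayrc.synthetic import (_render_frame, _node_textures,
                                      SwayConfig)
        cfg = SwayConfig(n_nodes=4, grid=(2, 2), node_spacing=60,
                         frame_shape=(160, 200))
        tex, tints = _node_textures(cfg)
        rest = cfg.rest_positions()
        frames = []
        for t in range(n_frames):
            pos = rest + t * np.asarray(velocity)
            frames.append(_render_frame(pos, tex, tints, cfg, t))
        return VideoClip(np.stack(frames), fps=60.0)

    def test_static_clip_constant_rows(self):
        clip = self._blob_clip((0.0, 0.0), n_frames=5)
        series = track_clip(clip)
        assert np.allclose(series.X, series.X[0], atol=1e-3)
        assert series.n_units == 8  # 4 blobs x 2 coordinates

    def test_rigid_translation_recovered(self):
        clip = self._blob_clip((0.5, 0.0))
        series = track_clip(clip)
        x_cols = series.X[:, 0::2]
        steps = np.diff(x_cols, axis=0)
        assert np.all(np.abs(steps - 0.5) < 0.1)

    def test_zero_points_raises(self):
        blank = VideoClip(np.full((3, 60, 60, 3), 90, np.uint8))
        with pytest.raises(ValueError):
            track_clip(blank)

    def test_csv_round_trip(self, tmp_path):
        clip = self._blob_clip((0.2, 0.1), n_frames=8)
        series = track_clip(clip)
        path = series.to_csv(tmp_path / "series.csv")
        back = series.from_csv(path)
        assert np.allclose(back.X, series.X)
        assert back.fps == series.fps
        assert np.array_equal(back.lost_mask, series.lost_mask)


@pytest.mark.skipif(not _kernels.HAVE_NUMBA, reason="numba not installed")
class TestKernelEquivalence:
    """The numba fast path must match the pure-numpy reference."""

    def test_pyramid_downsample(self, textured_image):
        img32 = textured_image.astype(np.float32)
        fast = _kernels.pyr_down(img32)
        ref = gaussian_pyramid(img32.astype(np.float64), 1)[1]
        assert fast.shape == ref.shape
        assert np.allclose(fast, ref, atol=1e-2)

    def test_tracking_paths_agree(self, monkeypatch):
        clip = TestTrackClip._blob_clip((0.4, -0.2), n_frames=15)
        fast = track_clip(clip)
        monkeypatch.setattr(_kernels, "HAVE_NUMBA", False)
        ref = track_clip(clip)
        assert np.allclose(fast.X, ref.X, atol=0.05)

    def test_rendered_luminance_paths_agree(self):
        from swayrc.synthetic import (_render_luminance, _render_frame,
                                      _node_textures, SwayConfig)
        from swayrc import rgb_to_luminance
        cfg = SwayConfig(n_nodes=4, grid=(2, 2), node_spacing=60,
                         frame_shape=(160, 200))
        tex, tints = _node_textures(cfg)
        pos = cfg.rest_positions() + 0.3
        fast = _render_luminance(pos, tex.astype(np.float32),
                                 tints.astype(np.float32), cfg)
        ref = rgb_to_luminance(_render_frame(pos, tex, tints, cfg))
        assert np.abs(fast - ref).max() <= 1.0  # uint8 quantization slack
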