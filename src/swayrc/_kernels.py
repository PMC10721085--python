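"""Optional numba-accelerated inner loops.

Every kernel here has a pure-numpy twin in the calling module; the numba
versions exist only to keep long video round trips fast on one core.
Equivalence of the two paths is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def paint_blobs(field, textures, tints, xs, ys):
    """Accumulate tinted textures into a zeroed (H, W, 3) float32 field.

    Blob i's patch textures[i] lands at (xs[i], ys[i]) with bilinear
    subpixel weighting.  Bounds are checked by the caller.
    """
    n = xs.shape[0]
    s = textures.shape[1]
    for i in range(n):
        ix = int(np.floor(xs[i]))
        iy = int(np.floor(ys[i]))
        fx = np.float32(xs[i] - ix)
        fy = np.float32(ys[i] - iy)
        rad = (s - 1) // 2
        top = iy - rad
        left = ix - rad
        for a in range(s):
            for b in range(s):
                v = textures[i, a, b]
                if v == 0.0:
                    continue
                w00 = v * (1 - fy) * (1 - fx)
                w01 = v * (1 - fy) * fx
                w10 = v * fy * (1 - fx)
                w11 = v * fy * fx
                for c in range(3):
                    t = tints[i, c]
                    field[top + a, left + b, c] += w00 * t
                    field[top + a, left + b + 1, c] += w01 * t
                    field[top + a + 1, left + b, c] += w10 * t
                    field[top + a + 1, left + b + 1, c] += w11 * t


@njit(cache=False)
def quantize_blobs(field, rgb, lum, xs, ys, rad, background, lum_weights):
    """Convert blob neighbourhoods of the field to uint8 RGB + luminance.

    rgb and lum must be pre-filled with the (quantized) background;
    pixels covered by more than one blob box are simply written twice
    with the same value.
    """
    h, w = lum.shape
    n = xs.shape[0]
    s = 2 * rad + 2
    for i in range(n):
        top = int(np.floor(ys[i])) - rad
        left = int(np.floor(xs[i])) - rad
        for a in range(s):
            r_ = top + a
            for b in range(s):
                c_ = left + b
                l = np.float32(0.0)
                for ch in range(3):
                    v = background + field[r_, c_, ch]
                    if v < 0.0:
                        v = 0.0
                    elif v > 255.0:
                        v = 255.0
                    q = np.uint8(v)
                    rgb[r_, c_, ch] = q
                    l += np.float32(q) * lum_weights[ch]
                lum[r_, c_] = l


@njit(cache=False)
def pyr_down(img):
    """Binomial 5-tap blur (replicated edges) then 2x decimation."""
    h, w = img.shape
    k = np.array([0.0625, 0.25, 0.375, 0.25, 0.0625], dtype=np.float32)
    tmp = np.empty((h, w), np.float32)
    for i in range(h):
        for j in range(w):
            acc = np.float32(0.0)
            for t in range(5):
                jj = j + t - 2
                if jj < 0:
                    jj = 0
                elif jj >= w:
                    jj = w - 1
                acc += img[i, jj] * k[t]
            tmp[i, j] = acc
    ho = (h + 1) // 2
    wo = (w + 1) // 2
    out = np.empty((ho, wo), np.float32)
    for i in range(ho):
        ii = 2 * i
        for j in range(wo):
            acc = np.float32(0.0)
            for t in range(5):
                kk = ii + t - 2
                if kk < 0:
                    kk = 0
                elif kk >= h:
                    kk = h - 1
                acc += tmp[kk, 2 * j] * k[t]
            out[i, j] = acc
    return out


@njit(cache=False, inline="always")
def _bil(img, y, x):
    h, w = img.shape
    if y < 0.0:
        y = 0.0
    elif y > h - 1.0:
        y = h - 1.0
    if x < 0.0:
        x = 0.0
    elif x > w - 1.0:
        x = w - 1.0
    y0 = int(np.floor(y))
    x0 = int(np.floor(x))
    if y0 > h - 2:
        y0 = h - 2
    if x0 > w - 2:
        x0 = w - 2
    fy = y - y0
    fx = x - x0
    return (img[y0, x0] * (1 - fy) * (1 - fx)
            + img[y0, x0 + 1] * (1 - fy) * fx
            + img[y0 + 1, x0] * fy * (1 - fx)
            + img[y0 + 1, x0 + 1] * fy * fx)


@njit(cache=False)
def lk_level(prev_lvl, next_lvl, px, py, g, lost, r, max_iter, eps, min_eig):
    """One pyramid level of iterative Lucas-Kanade for all points.

    px, py: point coordinates at this level; g (n, 2) holds the incoming
    flow guess at this level's scale and is updated in place with the
    refined flow.  lost is set for gradient-deficient windows.
    """
    n = px.shape[0]
    w = 2 * r + 1
    t_win = np.empty((w, w))
    tx = np.empty((w, w))
    ty = np.empty((w, w))
    for p in range(n):
        if lost[p]:
            continue
        # template and its gradients from one padded sample grid
        g11 = 0.0
        g12 = 0.0
        g22 = 0.0
        for a in range(w):
            yy = py[p] + a - r
            for b in range(w):
                xx = px[p] + b - r
                t_win[a, b] = _bil(prev_lvl, yy, xx)
                dx = (_bil(prev_lvl, yy, xx + 1.0)
                      - _bil(prev_lvl, yy, xx - 1.0)) / 2.0
                dy = (_bil(prev_lvl, yy + 1.0, xx)
                      - _bil(prev_lvl, yy - 1.0, xx)) / 2.0
                tx[a, b] = dx
                ty[a, b] = dy
                g11 += dx * dx
                g12 += dx * dy
                g22 += dy * dy
        half_tr = (g11 + g22) / 2.0
        disc = ((g11 - g22) / 2.0) ** 2 + g12 * g12
        mineig = half_tr - np.sqrt(disc)
        if mineig < min_eig:
            lost[p] = True
            continue
        det = g11 * g22 - g12 * g12
        dxp = 0.0
        dyp = 0.0
        for _ in range(max_iter):
            b1 = 0.0
            b2 = 0.0
            for a in range(w):
                yy = py[p] + a - r + g[p, 1] + dyp
                for b in range(w):
                    xx = px[p] + b - r + g[p, 0] + dxp
                    err = _bil(next_lvl, yy, xx) - t_win[a, b]
                    b1 -= tx[a, b] * err
                    b2 -= ty[a, b] * err
            ix = (g22 * b1 - g12 * b2) / det
            iy = (g11 * b2 - g12 * b1) / det
            dxp += ix
            dyp += iy
            if np.sqrt(ix * ix + iy * iy) < eps:
                break
        g[p, 0] += dxp
        g[p, 1] += dyp


@njit(cache=False)
def sway_steps(rest, k, steady, noise, damping, coupling, ramp, bound):
    """Integrate the damped coupled oscillator chain.

    rest (n, 2), k (n, 1) stiffness, steady (n, 2) steady force,
    noise (T-1, n, 2) pre-drawn force noise, ramp (T-1,) forcing ramp.
    Returns positions (T, n, 2); positions[0] is rest.  Returns an array
    of NaN if the dynamics diverge (caller raises).
    """
    steps = noise.shape[0] + 1
    n = rest.shape[0]
    out = np.empty((steps, n, 2))
    d = np.zeros((n, 2))
    v = np.zeros((n, 2))
    for i in range(n):
        out[0, i, 0] = rest[i, 0]
        out[0, i, 1] = rest[i, 1]
    acc = np.empty((n, 2))
    for t in range(1, steps):
        rmp = ramp[t - 1]
        for i in range(n):
            for c in range(2):
                lap = 0.0
                if i > 0:
                    lap += d[i - 1, c] - d[i, c]
                if i < n - 1:
                    lap += d[i + 1, c] - d[i, c]
                force = rmp * (steady[i, c] + noise[t - 1, i, c])
                acc[i, c] = -k[i, 0] * d[i, c] - damping * v[i, c] \
                    + coupling * lap + force
        for i in range(n):
            for c in range(2):
                v[i, c] = v[i, c] + acc[i, c]
                d[i, c] = d[i, c] + v[i, c]
                if np.abs(d[i, c]) > bound:
                    out[:, :, :] = np.nan
                    return out
                out[t, i, c] = rest[i, c] + d[i, c]
    return out
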