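# Methods

This note records the models, conventions and numerical choices behind
`swayrc`, and what the synthetic benchmark does and does not establish.

## Pipeline conventions

**Preprocessing.** Video frames are reduced with k×k max pooling
(default k = 3) applied per RGB channel — max pooling preserves the
small high-contrast structures corner detection needs — and then
converted to luminance. The luminance weights are Rec.601
(0.299, 0.587, 0.114); any fixed convex combination would serve, so we
use the most common convention. Pooling uses ceil-division blocks, so
ragged edges produce smaller final blocks (1920×1080 → 640×360 is
exact). Images are row-major, origin top-left, x = column, y = row,
0-based; subpixel reads are bilinear with edge clamping.

**Corner detection.** The structure tensor is accumulated over a 7×7
patch from central-difference gradients (edges replicated). The
Shi–Tomasi response is the smaller eigenvalue, computed in closed form;
the Harris form `det − k·trace²` is available. The acceptance threshold
is `R > quality_fraction · R_max` with `quality_fraction = 0.01`: an
absolute threshold equal to `R_max` itself would accept nothing, and a
fractional threshold also makes detection invariant to affine intensity
rescaling. Non-maximum suppression is greedy in decreasing response
(ties broken by (y, x)), enforcing a 20 px minimum separation; this
makes detection fully deterministic.

**Tracking.** Iterative Lucas–Kanade over a 15×15 window, refined up to
10 iterations per level or until the update falls below 0.01 px, on a
3-level Gaussian pyramid (5-tap binomial blur, 2× decimation, quarter
area per level). The spatial-gradient matrix comes from the previous
frame's window; a point is declared lost when that matrix's smallest
eigenvalue falls below `min_eigen_threshold` (default 1e-3, an absolute
value on the window sum) or the track leaves the image. Lost points
keep their last valid coordinates and are flagged, so the state matrix
stays rectangular — the readout needs a fixed number of columns.
Tracking runs streaming (one frame in memory at a time); when numba is
installed the per-window loops, pyramid construction, blob rendering
and oscillator integration use compiled kernels whose pure-numpy twins
remain the reference implementation (equivalence is tested; the two
paths agree to float32 rounding and ±1 uint8 quantization).

## Readout

Ridge weights are the exact closed form `W = YᵀX(XᵀX+αI)⁻¹`, computed
by a symmetric solve, with **no intercept**: on raw pixel coordinates
the large constant component of X acts as an implicit intercept, which
is the same mechanism that lets the readout "adapt to the size of the
coordinates". The default α = 10⁶ is tied to that raw-coordinate
scale. For **standardized** inputs (zero mean, unit population
variance, statistics from training rows only, variances floored at
1e-12 with a warning) the same absolute α would be orders of magnitude
stronger relative to the data and collapses speed classes; experiment
drivers on standardized data therefore default to a scale-commensurate
α = 10³. Classification is the arg-max of a τ-step trailing moving
average of the scores (τ = 30 ≈ 0.5 s at 60 FPS, configurable and
reported with every result); the window is truncated at the series
start and reset at recording boundaries, because the benchmark's class
segments are separate recordings and smoothing across them would mix
conditions. Ties break to the smallest class index. Cross-entropy is
evaluated after clipping scores to [1e-12, 1]; applied to raw ridge
scores (which are not probabilities) it is a diagnostic, not a proper
likelihood. The multinomial-logistic readout is a maximum-likelihood
softmax fit (LBFGS, unpenalized, ≤1500 iterations; non-convergence on
separable data is flagged, not raised) reported in reference-class form:
K−1 coefficient rows, last class fixed at zero.

Splits are chronological per recording (first 70% train, last 30%
test) — shuffled splits would leak the strong temporal autocorrelation
of sway into the test set.

## Synthetic plant and benchmark

The generator emulates a desk-scale version of a foliage plant in front
of a directional fan. 24 nodes sit on a 6×4 grid (70 px spacing) in
640×544 frames at 60 FPS. Each node is a discrete-time damped 2-D
oscillator (stiffness 0.02 frame⁻², damping 0.4 frame⁻¹, chain coupling
0.01 frame⁻², explicit Euler per frame — exactly reproducible, which an
ODE solver would not be), pulled toward its rest position and driven by
the wind force plus i.i.d. Gaussian gust noise whose scale grows with
fan level (0.02 px frame⁻² per level).

The steady force encodes the class through a deliberately nonlinear,
leaf-specific response, because a reservoir is only useful if its state
is a nonlinear transform of the input — a plant whose deflection were
proportional to wind speed would give collinear class means that no
linear readout at α = 10⁶ could separate. Per leaf: a saturating drag
magnitude `D·g·tanh(s/s₀)` (terminal deflection ≈ 57 px, gains
log-normal ±20%, saturation speeds log-normal around level 1.5); a curl
("tuck") factor with its own onset speed near level 5 that makes
deflection recede at high load for some leaves (non-monotone
responses); a swing direction that starts along the leaf's own petiole
hinge (the wind force projected onto a random fixed axis) and realigns
toward the wind as load grows (alignment scale ≈ level 6); a
load-dependent twist (σ = 30°); and a signed vertical droop/lift
(±, mostly downward). All leaf parameters derive from a plant-specific
RNG stream, so every wind condition shows the same plant.

Each class is simulated and rendered as its own clip beginning from the
identical rest frame: the forcing ramps up over 90 frames and the first
150 frames are excluded from the labelled series, mimicking recordings
that start after the fan has been switched on. Because all clips share
frame 0, a single corner detection aligns the tracked columns across
conditions. Recording protocol: 2880 labelled frames (48 s) per
condition for the six-class study; 720 frames (12 s) per condition for
the 24-class study, which has four times as many conditions. Nodes are
rendered as 19 px textured blobs (smoothed noise under a raised-cosine
window, greenish per-node tints, background 128) placed with bilinear
subpixel accuracy; blob positions are bounds-checked before rendering.

**What passing the synthetic benchmark shows — and what it does not.**
It shows the complete pipeline (pooling, detection, pyramidal LK,
ridge/logistic readout, all four experiment drivers) is implemented
correctly and that the reservoir premise works end-to-end at desk
scale: tracked trajectories of a nonlinearly responding structure are
linearly separable by wind class, redundantly across units, with
direction generalization and graceful degradation. It does not certify
performance on real footage: real plants have occlusions, out-of-plane
motion, appearance changes, camera noise and re-detection needs, none
of which the renderer produces; and the generator's class conditions
are stationary within a recording, whereas real wind drifts.

## Numerical and design choices

- Detection margin: responses within half a patch of the border are
  excluded (gradient support would be clipped).
- Gaussian pyramid levels must keep ≥4 px per side; deeper requests
  raise.
- LK window gradients are central differences sampled from one padded
  bilinear grid — identical values, a third of the samples.
- `subsample_experiment` precomputes the training Gram matrix once, so
  1000 ridge retrains on unit subsets cost little more than one fit.
- Weight ablation removes units in feature-point pairs (both
  coordinates of a point vanish together, as a lost sensor would),
  ranked by the basis class's absolute weights; `order` chooses
  increasing (default) or decreasing removal because either reading of
  "importance" is defensible, and the weights are never retrained.
- Delay augmentation builds `X′(t) = [X(t), X(t+τ), …, X(t+dτ)]`
  per contiguous recording segment, so no augmented row mixes
  recordings or lets training windows reach into test frames.
- Seeds: every stochastic component (plant parameters, textures,
  turbulence, subset draws) derives from explicit `SeedSequence`
  streams; identical seeds give byte-identical series.
- Clip files: multi-page TIFF and `.npz` are the canonical on-disk
  formats (no extra codecs needed); MP4/AVI are delegated to imageio
  and require an ffmpeg plugin where available.

## Known limitations

- No feature re-detection or replenishment mid-clip; long clips slowly
  lose points if the scene changes (the synthetic benchmark does not).
- The renderer's global tints and flat background make detection easier
  than natural foliage; `quality_fraction` likely needs tuning on real
  video.
- Training accuracy under delay augmentation is not strictly monotone
  in d on noisy tracked data at α = 10⁶ (small drifts ≲0.03 after the
  initial rise); the documented guarantee is net non-harm plus large
  gains for unit-poor subsets.
- Ridge with α = 10⁶ on *standardized* desk-scale data approaches a
  correlation-template classifier and separates direction but not
  speed; use the scale-commensurate default (α = 10³) or raw
  coordinates.
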