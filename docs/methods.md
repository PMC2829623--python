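# Methods

`myotrace` quantifies the contraction of an isolated adult cardiac myocyte
from bright-field video as a *two-dimensional* shape change, rather than the
one-dimensional length change a raster-line edge detector reports. This note
records the models, the numerical choices, and the limits of what the test
suite demonstrates.

## Pipeline model

Each frame passes through five stages:

1. **TV smoothing** — edge-preserving denoising by the evolution
   `u_t = |∇u| ∇·(g ∇u) − Λ(u − u₀)` with `g = 1/√(u_x² + u_y² + ε)`,
   `ε = 1/255`.
2. **Segmentation** — Otsu two-class thresholding (dark cell on bright
   background by default), 3×3 morphological closing, hole filling,
   largest-component selection.
3. **Contour extraction** — marching-squares iso-contour, circular Gaussian
   smoothing of the coordinate functions, arclength-uniform resampling to
   `2^M` vertices (default `M = 7`, 128 points).
4. **Fourier descriptors** — normalized DFT `Q(k) = (1/N) Σ q(n) e^{−j2πkn/N}`
   of a boundary signature, made invariant to translation, rotation and
   starting point but *deliberately scale-covariant*; the first `K = 30`
   magnitudes are kept.
5. **Contractility** — per-frame percent distance
   `d(t) = 100·‖a_t − b‖₂/‖b‖₂` from a reference (most-relaxed) frame,
   twitch detection, transient averaging, range normalization.

## TV smoothing: dynamics and numerics

The fidelity weight `Λ = −(1/2σ²) ∇uᵀ·(∇u − ∇u₀)` is recomputed every
iteration with the noise variance estimated as `σ² = var(u) − var(G_σ∗u)`
(unit-sum Gaussian, width 1 px, truncated at 3σ). The per-pixel step
`δt = ε/5 + (1/(2d) − ε/5)(max|∇u| − |∇u|)/max|∇u|` is largest (1/4 for
d = 2) in flat regions and smallest at the strongest edge.

Three numerical decisions matter:

* **Stability clamp.** The explicit scheme is unconditionally unstable as
  written: as the evolution denoises, `σ² → 0` makes `Λ` unbounded, and
  negative `Λ` (wherever the evolving gradient exceeds the observed one)
  amplifies `u − u₀` exponentially — on our synthetic fixtures the blowup
  arrives near iteration 70. `Λ` is therefore clamped to `[0, 1/δt]`, the
  exact stability range of the explicit fidelity relaxation. A pixel clamped
  at `1/δt` snaps back to the observation in one step instead of
  overshooting.
* **Conservative face-centered stencil.** `∇·(g ∇u)` uses forward-difference
  fluxes on half-grid faces with `g` evaluated from the face-centered
  gradient (normal one-sided difference + averaged tangential central
  difference), then a backward-difference divergence. Evaluating `g` per
  pixel and averaging onto faces lets the huge flat-region diffusivity
  `1/√ε ≈ 16` leak into edge fluxes and measurably blurs edges. Border
  fluxes are zero, which realizes `⟨g·∇u, n⟩ = 0` exactly.
* **Retention rule.** Per iteration we record `c̄ = corr(u, u₀)` and keep the
  current image while the *first difference of* `ĉ = ∂²c̄` is ≤ 0, i.e.
  while the decay of the image–observation correlation has not begun
  decelerating for good; the first three iterates are always kept. Keying on
  `ĉ ≤ 0` itself retains almost nothing — `c̄` decays convexly from
  iteration 1 — while the measurable restoration quality (correlation with
  the clean scene, available in simulation) keeps improving deep into the
  run, which is what motivated this reading.

Two intrinsic properties of the model are worth knowing. The variance
estimator also removes *edge* variance when it blurs, so on sharp-edged
scenes it overestimates the noise floor (on a 256×256 rod with injected
variance 10⁻³ the raw estimate is about 2× high; the bias cancels in the
difference `est(clean+η) − est(clean)`, which is what the unit test checks).
And because `Λ ≤ 0` wherever the *observation* is flat, nothing anchors the
pixels just outside an edge: a sharp step relaxes into a ramp a few pixels
wide. The mid-edge crossing stays put (the segmentation boundary moves < 1
px) but per-pixel differences inside a ~5 px band around the edge can reach
0.1–0.2. Both are properties of the model, not of the discretization.

## Segmentation and contours

Otsu thresholding is computed on the image (or its negation, for
`bright-cell` polarity), making inversion symmetry exact. Post-processing
guarantees the downstream contract: exactly one hole-free foreground
component.

Contours extracted from the *binary* mask have vertices quantized to
half-integer grid midpoints, and that quantization is orientation-dependent:
through the full pipeline it contributed a systematic ~0.5% (of a ~7% peak)
offset to the trace of a rotated cell. `extract_contour` therefore accepts
the smoothed intensity image and re-localizes the boundary as the
iso-contour at the segmentation threshold — genuinely sub-pixel vertex
placement. The pipeline uses this path; the mask-only path remains for
callers that have nothing but a mask.

Contour smoothing (circular Gaussian, σ = 2 vertex units, truncated at 3σ)
suppresses segmentation pixel noise without moving the centroid. Resampling
places `2^M` points at equal arclength along the closed polyline, starting
at the original first vertex; the descriptor normalization removes any
residual starting-point dependence.

## Descriptors: which invariances, and why not scale

Two signatures are available: complex coordinates `q(n) = x(n) + j·y(n)`
and the centroid distance `r(n) = ‖p(n) − (x_c, y_c)‖` (the default —
real-valued, hence conjugate-symmetric with only N/2 distinct frequencies,
and translation-invariant by construction). Normalization: zero `Q(0)`
(complex-coords only — it is the centroid), multiply by `e^{−jφ₁k}` with
`φ₁ = atan2(Im Q(1), Re Q(1))` for starting-point invariance, then take
magnitudes for rotation invariance. The two-argument arctangent avoids the
quadrant ambiguity of a plain `tan⁻¹`. If `Q(1)` vanishes exactly (perfectly
symmetric shapes) the phase reference falls back to the lowest nonzero
coefficient and warns; magnitudes make the choice irrelevant, but it keeps
the intermediate deterministic.

Scale is *not* normalized: uniform scaling multiplies every magnitude by the
scale factor, which is precisely what lets the descriptor distance register
a contraction. The DC term is kept for the centroid-distance method (it is
the mean radius — genuine size information) and excluded for complex-coords.

`descriptor_distance(a, b) = 100·‖a − b‖₂/‖b‖₂` normalizes by the
*reference* norm so that uniform scaling by `s` reads exactly `(1−s)·100` %,
the natural two-dimensional analog of percent shortening. For anisotropic
shape change there is no such closed form: for the synthetic cell's default
contraction (length ×0.9, width ×0.9^{−1/2}), direct geometric computation
gives a peak distance of ≈ 6.7–7.1 %, not 10 % — the descriptor vector does
not change along a single ray, so its displacement norm is smaller than the
length-strain alone would suggest. The acceptance measurements report the
value actually computed.

## Reference frame and twitch analysis

The default reference policy picks the frame with the maximal descriptor
norm — the most relaxed shape — because recordings may start mid-twitch;
`first` and explicit-index policies exist. Twitches are peaks with
prominence ≥ 0.3 × trace range; each twitch window is 0.8 × the median
inter-peak interval, centered on the upstroke half-maximum crossing
(linearly interpolated), and windows that run off the trace ends are dropped
from the average. The normalized trace maps the range to [0, 1].

## Raster-line baseline

The classic baseline scans one image row and reports the distance between
the first and last sub-threshold crossings (sub-pixel, by linear
interpolation). It measures extent along its row only: when the cell lies
perpendicular to the row it tracks the cell *width*, so with the synthetic
cell's width bulge it still sees roughly half the length signal
(width strain `(1−s)^{−1/2} − 1 ≈ s/2`), and with the bulge disabled it sees
essentially nothing. This quantifies, rather than merely asserts, what a 1-D
measurement misses.

## Synthetic data: what it emulates and what it does not

The generator renders a stadium-shaped (rounded-rectangle) silhouette —
100 µm × 25 µm at 0.5 µm/px by default — dark (0.25) on bright (0.80), with
anti-aliased edges (linear coverage over a one-pixel band from the signed
distance to the boundary polygon), i.i.d. Gaussian sensor noise
(σ = 0.02), pacing at 0.33 Hz recorded at 30 frames/s, and a twitch
waveform with a 0.1 s linear upstroke to 10 % peak shortening followed by
exponential relaxation (τ = 0.25 s) — fast shortening, slower recovery. At
shortening `s` the silhouette scales lengthwise by `1−s` and widthwise by
`(1−s)^{width_exponent}`; the default exponent −1/2 is the bulge of an
incompressible 3-D body in 2-D projection (projected area ∝ √(1−s)),
exponent 0 disables the bulge and −1 preserves projected area exactly.
Optional rigid rotation/translation ramps emulate the cell drifting or
torquing during recording; optional seeded radial noise at the cap ends
emulates the jagged gap-junction ends of real myocytes. All randomness
derives from one seed; identical seeds give bit-identical videos.

What it does **not** emulate: sarcomere striation texture, out-of-plane
motion and defocus, illumination gradients, intensity flicker, neighboring
cells or debris, and spatially nonuniform contraction (bending). Passing
tests therefore demonstrate correctness of the machinery and its stated
invariances under this controlled imaging model — not segmentation
robustness on adverse real recordings.

## Problem sizes

End-to-end tests and the acceptance script run the 12 s / 0.33 Hz / 30 fps
protocol at 1 µm/px (cell 100 × 25 px, frames ≈ 52 × 124), a size chosen so
the complete suite finishes in a few minutes; the single-frame TV and
segmentation checks use 256 × 256 frames at the default 0.5 µm/px. Larger
rasters change none of the qualitative results.

## Known limitations

* Single cell per frame; touching or overlapping cells are out of scope.
* The segmentation stand-in is a global two-class threshold; heavy
  vignetting would require a local method behind the same interface.
* The descriptor trace is a relative measure against a within-recording
  reference; absolute calibration (µm of shortening) requires the raster
  baseline or the pixel size plus a geometric model.
* The stopping rule for TV smoothing is heuristic; with the default 100
  iterations it retains a late, well-denoised iterate on our fixtures, but
  pathological inputs could retain an earlier one.
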