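# myotrace

Video-based assessment of contractility in isolated adult cardiac myocytes.

Isolated rod-shaped ventricular myocytes (~100 µm × 25 µm) are a workhorse
of cardiovascular research: paced by field stimulation, they twitch, and the
magnitude and kinetics of that twitch report on excitation–contraction
coupling, drug effects, and disease models. The classic measurement — a
raster line tracking the threshold crossings of one video scan line — sees
only the cell's extent along that line and is confounded whenever the cell
rotates, translates, or bends. `myotrace` instead measures contraction as a
change of the *whole two-dimensional boundary shape*:

1. **TV smoothing** — each frame is denoised by the edge-preserving total
   variation evolution `u_t = |∇u| ∇·(g ∇u) − Λ(u − u₀)`,
   `g = 1/√(u_x² + u_y² + ε)`, with a dynamic fidelity weight
   `Λ = −(1/2σ²) ∇uᵀ·(∇u − ∇u₀)` and per-pixel time step
   `δt ∈ [ε/5, 1/(2d)]`.
2. **Segmentation** — automatic two-class thresholding plus morphological
   cleanup yields one hole-free cell mask per frame.
3. **Contour** — the sub-pixel boundary is extracted, smoothed by circular
   Gaussian convolution, and resampled to `2^M` arclength-uniform points.
4. **Fourier descriptors** — from a boundary signature (centroid distance
   `r(n) = ‖p(n) − (x_c, y_c)‖` by default, or complex coordinates
   `q(n) = x(n) + j·y(n)`), the normalized DFT
   `Q(k) = (1/N) Σ_n q(n) e^{−j2πkn/N}` is made invariant to translation,
   rotation and starting point — but **not** to scale, so shape change
   registers. The first `K = 30` magnitudes are kept.
5. **Contraction trace** — frame `t` scores
   `d(t) = 100·‖a_t − b‖₂/‖b‖₂` percent against the most-relaxed reference
   frame; a uniform contraction by `s` reads exactly `(1−s)·100` %. Twitches
   are detected, aligned at their upstroke half-maximum, and averaged.

A raster-line baseline (`raster_line_trace`) and a synthetic video generator
(`render_video`: stadium-shaped cell, paced twitch waveform, sensor noise,
optional rigid motion, full ground truth) are included, so every stage is
testable without real recordings. See `docs/methods.md` for the models,
numerical choices, and limitations.

## Worked example

```python
import myotrace as mt
from myotrace.pipeline import PipelineConfig, process_sequence

# a 12 s recording at 30 fps: 0.33 Hz pacing, 10% peak shortening, 1 µm/px
video = mt.render_video(
    mt.CellModel(pixel_size=1.0),
    mt.TwitchProtocol(duration=12.0, seed=7),
)
art = process_sequence(video.sequence, PipelineConfig())
rec = art["record"]
print(f"frames analyzed : {len(rec)}")
print(f"twitches found  : {len(rec.twitch_peaks)}")
print(f"peak contraction: {rec.values.max():.2f}%")
print(f"reference frame : {rec.reference_frame}")
```

prints

```
frames analyzed : 360
twitches found  : 4
peak contraction: 7.12%
reference frame : 231
```

All four paced twitches are recovered; the dominant frequency of the trace
is 0.333 Hz, the pacing rate. The peak reads 7.12 % rather than the naive
10 % because the shortening is anisotropic (the cell bulges widthwise as it
shortens lengthwise), and the descriptor distance measures the full 2-D
shape change, not length strain alone — see `docs/methods.md`.

The same pipeline runs from the shell:

```sh
myotrace synth --duration 12 --seed 7 --output video.tif
myotrace trace --input video.tif --outdir out/       # writes out/trace.csv
myotrace compare --input video.tif --outdir out/     # + raster-line baseline
```

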