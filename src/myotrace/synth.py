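"""Synthetic bright-field videos of a contracting rod-shaped myocyte.

The simulated cell is a stadium (a rectangle with semicircular caps) of
~100 µm × 25 µm — the canonical geometry of an isolated adult ventricular
myocyte — rendered dark (default 0.25) on a bright background (0.80), the
bright-field contrast the segmentation stage expects.

Pacing follows a periodic twitch waveform s(t): a fast linear upstroke over
``rise_time`` to the peak fractional shortening ``amplitude``, then an
exponential relaxation with time constant ``relax_tau`` — the fast-
shortening / slower-recovery asymmetry of a real stimulus-evoked twitch.
At fractional shortening s the silhouette is scaled lengthwise by (1 − s)
and widthwise by (1 − s)^{width_exponent}; the default exponent −1/2 is the
widthwise bulge of an incompressible three-dimensional cell (volume
preserved) seen in two-dimensional projection, so the projected area follows
(1 − s)^{1/2}. Exponent 0 disables the bulge; −1 preserves projected area
exactly.

Frames are rasterized with anti-aliased edges (linear coverage over a
one-pixel band around the silhouette boundary, from the signed distance to
the boundary polygon), then i.i.d. Gaussian sensor noise is added and
clipped to [0, 1]. Every frame carries full ground truth: the binary mask,
the boundary polygon, and the shortening value. All randomness flows from
one explicit seed; identical seeds give bit-identical videos.

Defaults follow the recording conditions the pipeline targets: 0.33 Hz
field stimulation captured at 30 frames/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree

from .contour import ClosedContour
from .errors import FrameOverflowError
from .videoio import FrameSequence


@dataclass
class CellModel:
    """Geometry and optics of the simulated cell."""

    length: float = 100.0  # µm
    width: float = 25.0  # µm
    pixel_size: float = 0.5  # µm per pixel
    end_jaggedness: float = 0.0  # radial noise amplitude at the cap ends, px
    cell_intensity: float = 0.25
    background_intensity: float = 0.80

    def __post_init__(self) -> None:
        if not self.length > self.width > 0:
            raise ValueError("need length > width > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.cell_intensity == self.background_intensity:
            raise ValueError("cell and background intensities must differ")


@dataclass
class TwitchProtocol:
    """Stimulation, acquisition and motion parameters of one recording."""

    pacing_rate: float = 0.33  # Hz
    frame_rate: float = 30.0  # frames per second
    duration: float = 12.0  # seconds
    amplitude: float = 0.10  # peak fractional lengthwise shortening
    rise_time: float = 0.1  # s
    relax_tau: float = 0.25  # s
    noise_sigma: float = 0.02  # intensity units
    width_exponent: float = -0.5  # widthwise bulge exponent (0 disables)
    orientation_deg: float = 0.0  # resting long-axis angle to the x axis
    rotation_ramp_deg: tuple[float, float] = (0.0, 0.0)  # start -> end
    translation_ramp_px: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 0.0),
        (0.0, 0.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pacing_rate < self.frame_rate / 4:
            raise ValueError("pacing_rate must be below frame_rate / 4")
        if not 0 <= self.amplitude < 0.5:
            raise ValueError("amplitude must lie in [0, 0.5)")
        if self.rise_time <= 0 or self.relax_tau <= 0:
            raise ValueError("rise_time and relax_tau must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class SynthVideo:
    """A rendered video bundled with its ground truth."""

    sequence: FrameSequence
    masks: list[np.ndarray]
    contours: list[ClosedContour]
    shortening: np.ndarray  # s(t) per frame
    cell: CellModel
    protocol: TwitchProtocol


def twitch_waveform(t, p: TwitchProtocol) -> np.ndarray:
    """Fractional shortening s(t): periodic fast rise, exponential decay.

    Exactly 0 at every period start; exactly ``amplitude`` at
    t = rise_time within each period.
    """
    t = np.asarray(t, dtype=np.float64)
    period = 1.0 / p.pacing_rate
    phase = np.mod(t, period)
    rising = phase < p.rise_time
    s = np.where(
        rising,
        p.amplitude * phase / p.rise_time,
        p.amplitude * np.exp(-(phase - p.rise_time) / p.relax_tau),
    )
    return s if s.shape else float(s)


def _stadium_polygon(
    cell: CellModel, n_vertices: int = 512, jag: np.ndarray | None = None
) -> np.ndarray:
    """Resting-cell boundary in pixel units, centered at the origin.

    Vertices are approximately uniform in arclength. ``jag`` is an optional
    per-vertex radial perturbation (pixels) emulating the jagged gap-junction
    ends of a real myocyte.
    """
    L = cell.length / cell.pixel_size
    W = cell.width / cell.pixel_size
    R = W / 2.0
    a = (L - W) / 2.0  # half-length of the straight section
    per_cap = np.pi * R
    per_side = 2.0 * a
    total = 2 * per_cap + 2 * per_side
    # arclength positions, then map to the boundary piecewise
    s = np.linspace(0.0, total, n_vertices, endpoint=False)
    pts = np.empty((n_vertices, 2))
    for i, si in enumerate(s):
        if si < per_cap:  # right cap, angle -pi/2 -> pi/2
            th = -np.pi / 2 + np.pi * si / per_cap
            pts[i] = (a + R * np.cos(th), R * np.sin(th))
        elif si < per_cap + per_side:  # top side, x: a -> -a
            u = si - per_cap
            pts[i] = (a - u, R)
        elif si < 2 * per_cap + per_side:  # left cap, pi/2 -> 3pi/2
            th = np.pi / 2 + np.pi * (si - per_cap - per_side) / per_cap
            pts[i] = (-a + R * np.cos(th), R * np.sin(th))
        else:  # bottom side, x: -a -> a
            u = si - 2 * per_cap - per_side
            pts[i] = (-a + u, -R)
    if jag is not None:
        r = np.hypot(pts[:, 0], pts[:, 1])
        with np.errstate(invalid="ignore"):
            unit = np.where(r[:, None] > 0, pts / r[:, None], 0.0)
        pts = pts + unit * jag[:, None]
    return pts


def _end_jag_profile(
    cell: CellModel, n_vertices: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Smooth seeded radial noise concentrated at the cap ends."""
    if cell.end_jaggedness <= 0:
        return None
    n_modes = 12
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    amp = rng.normal(size=n_modes)
    phs = rng.uniform(0, 2 * np.pi, size=n_modes)
    noise = sum(
        a * np.cos((m + 3) * t + p) for m, (a, p) in enumerate(zip(amp, phs))
    )
    noise = noise / max(np.abs(noise).max(), 1e-12)
    pts = _stadium_polygon(cell, n_vertices)
    half_len = 0.5 * cell.length / cell.pixel_size
    end_weight = (np.abs(pts[:, 0]) / half_len) ** 6  # ~1 at caps, ~0 mid-cell
    return cell.end_jaggedness * noise * end_weight


def _rasterize(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Anti-aliased coverage of a polygon on the pixel grid.

    Coverage = clip(0.5 + signed_distance, 0, 1): a linear one-pixel edge
    model using the distance to a densified boundary (positive inside).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    # densify boundary for an accurate distance field
    closed = np.vstack([polygon, polygon[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n_dense = max(int(cum[-1] * 4), 256)
    t = np.linspace(0.0, cum[-1], n_dense, endpoint=False)
    dense = np.column_stack(
        [np.interp(t, cum, closed[:, 0]), np.interp(t, cum, closed[:, 1])]
    )
    dist, _ = cKDTree(dense).query(pix, workers=1)
    inside = MplPath(polygon).contains_points(pix)
    sd = np.where(inside, dist, -dist)
    return np.clip(0.5 + sd, 0.0, 1.0).reshape(shape)


def _frame_shape(
    cell: CellModel, p: TwitchProtocol, margin: int = 12
) -> tuple[int, int]:
    """Frame size accommodating the cell at every scale/rotation extreme."""
    base = _stadium_polygon(cell, 256)
    half_x = half_y = 0.0
    for sv in (0.0, p.amplitude):
        scale = np.array([1.0 - sv, (1.0 - sv) ** p.width_exponent])
        for rdeg in {p.rotation_ramp_deg[0], p.rotation_ramp_deg[1]}:
            ang = np.deg2rad(p.orientation_deg + rdeg)
            c_, s_ = np.cos(ang), np.sin(ang)
            poly = (base * scale) @ np.array([[c_, -s_], [s_, c_]]).T
            half_x = max(half_x, float(np.abs(poly[:, 0]).max()))
            half_y = max(half_y, float(np.abs(poly[:, 1]).max()))
    tx = max(abs(v[0]) for v in p.translation_ramp_px)
    ty = max(abs(v[1]) for v in p.translation_ramp_px)
    w = int(np.ceil(2 * (half_x + tx))) + 2 * margin
    h = int(np.ceil(2 * (half_y + ty))) + 2 * margin
    return (h + h % 2, w + w % 2)


def silhouette_sequence(
    cell: CellModel | None = None,
    p: TwitchProtocol | None = None,
    n_boundary: int = 512,
) -> tuple[list[ClosedContour], np.ndarray]:
    """Ground-truth boundary polygons per frame, without rasterizing.

    Applies the same per-frame scale/rotation/translation chain as
    :func:`render_video` (centered at the origin, no frame clipping) and
    returns the contours together with the shortening trace s(t). Useful for
    testing the descriptor and contraction stages in isolation from the
    imaging stages.
    """
    cell = cell or CellModel()
    p = p or TwitchProtocol()
    rng = np.random.default_rng(p.seed)
    jag = _end_jag_profile(cell, n_boundary, rng)
    base = _stadium_polygon(cell, n_boundary, jag)

    n = p.n_frames
    times = np.arange(n) / p.frame_rate
    s = np.atleast_1d(np.asarray(twitch_waveform(times, p)))
    frac = times / times[-1] if n > 1 else np.zeros(n)
    rot = np.deg2rad(
        p.orientation_deg
        + p.rotation_ramp_deg[0]
        + (p.rotation_ramp_deg[1] - p.rotation_ramp_deg[0]) * frac
    )
    (tx0, ty0), (tx1, ty1) = p.translation_ramp_px
    drift = np.column_stack([tx0 + (tx1 - tx0) * frac, ty0 + (ty1 - ty0) * frac])

    contours = []
    for i in range(n):
        scale = np.array([1.0 - s[i], (1.0 - s[i]) ** p.width_exponent])
        c, si = np.cos(rot[i]), np.sin(rot[i])
        poly = (base * scale) @ np.array([[c, -si], [si, c]]).T + drift[i]
        contours.append(ClosedContour(points=poly, frame_index=i))
    return contours, s


def render_video(
    cell: CellModel | None = None,
    p: TwitchProtocol | None = None,
    shape: tuple[int, int] | None = None,
    n_boundary: int = 512,
) -> SynthVideo:
    """Render a contracting-cell video with full ground truth.

    Per frame: the resting silhouette is scaled lengthwise by 1 − s(t) and
    widthwise by (1 − s(t))^{width_exponent} about its centroid, rotated and
    translated along the protocol's motion ramps, rasterized with
    anti-aliased edges, and corrupted with seeded Gaussian sensor noise.
    """
    cell = cell or CellModel()
    p = p or TwitchProtocol()
    shape = shape or _frame_shape(cell, p)
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    centered, s = silhouette_sequence(cell, p, n_boundary)
    rng = np.random.default_rng(p.seed)

    frames, masks, contours = [], [], []
    for i in range(p.n_frames):
        poly = centered[i].points + center
        if (
            poly[:, 0].min() < 1
            or poly[:, 1].min() < 1
            or poly[:, 0].max() > w - 2
            or poly[:, 1].max() > h - 2
        ):
            raise FrameOverflowError(f"cell leaves the frame at frame {i}")
        coverage = _rasterize(poly, shape)
        clean = cell.background_intensity + (
            cell.cell_intensity - cell.background_intensity
        ) * coverage
        noisy = clean + rng.normal(0.0, p.noise_sigma, size=shape) if p.noise_sigma > 0 else clean
        frames.append(np.clip(noisy, 0.0, 1.0))
        masks.append(coverage >= 0.5)
        contours.append(ClosedContour(points=poly.copy(), frame_index=i))

    seq = FrameSequence(
        frames=frames,
        frame_rate=p.frame_rate,
        pixel_size=cell.pixel_size,
        source=f"synth(seed={p.seed})",
    )
    return SynthVideo(
        sequence=seq, masks=masks, contours=contours, shortening=s,
        cell=cell, protocol=p,
    )
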