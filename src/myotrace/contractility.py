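"""From per-frame descriptor vectors to a contraction record.

The contraction measure of frame t is the Euclidean distance between its
descriptor-magnitude vector and that of a reference (most relaxed) frame,
normalized by the reference norm and expressed in percent:

    d(t) = 100 · ‖a_t − b‖₂ / ‖b‖₂.

Because descriptor magnitudes are linear in uniform scale, a uniform
contraction of the boundary by factor s gives exactly (1 − s)·100 % — the
two-dimensional analog of percent shortening. The raster-line baseline
(threshold crossings of one intensity row) is provided for comparison; it
tracks only the extent of the cell along its row and is blind to shape
change perpendicular to it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .descriptors import DescriptorVector
from .errors import NoEdgeError, NoTwitchError, ZeroNormError


@dataclass
class ContractionRecord:
    """Per-frame contraction values plus twitch analysis results."""

    times: np.ndarray
    values: np.ndarray  # percent descriptor distance from the reference
    reference_frame: int
    normalized: np.ndarray | None = None
    twitch_peaks: np.ndarray | None = None
    mean_transient: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RasterLineRecord:
    """Cell extent along one raster row, per frame."""

    times: np.ndarray
    lengths: np.ndarray  # pixels
    row: int
    threshold: float

    def shortening_percent(self) -> np.ndarray:
        """Lengths as percent shortening relative to the maximum extent."""
        ref = float(np.max(self.lengths))
        if ref <= 0:
            raise ZeroNormError("raster reference length is zero")
        return 100.0 * (ref - self.lengths) / ref


def descriptor_distance(a: DescriptorVector, b: DescriptorVector) -> float:
    """Percent Euclidean distance between descriptor vectors, 100·‖a−b‖/‖b‖.

    ``b`` is the reference; its norm sets the scale so that a uniform
    contraction by s reads (1 − s)·100 %.
    """
    if a.method != b.method:
        raise ValueError(f"method mismatch: {a.method!r} vs {b.method!r}")
    if a.K != b.K:
        raise ValueError(f"descriptor count mismatch: {a.K} vs {b.K}")
    nb = b.norm()
    if nb == 0.0:
        raise ZeroNormError("reference descriptor vector has zero norm")
    return 100.0 * float(np.linalg.norm(a.magnitudes - b.magnitudes)) / nb


def contraction_trace(
    vectors: Sequence[DescriptorVector],
    frame_rate: float = 30.0,
    reference: int | str = "max-norm",
) -> ContractionRecord:
    """Build the per-frame contraction trace from descriptor vectors.

    Parameters
    ----------
    vectors : sequence of DescriptorVector
        One per frame, same method and K.
    frame_rate : float
        Frames per second; sets the time axis.
    reference : "max-norm", "first", or int
        Reference-frame policy. ``max-norm`` picks the frame with the
        largest descriptor norm — the most relaxed (largest) shape — which
        is robust to recordings that start mid-twitch.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 frames for a contraction trace")
    if reference == "max-norm":
        ref_idx = int(np.argmax([v.norm() for v in vectors]))
    elif reference == "first":
        ref_idx = 0
    elif isinstance(reference, (int, np.integer)):
        ref_idx = int(reference)
        if not 0 <= ref_idx < len(vectors):
            raise ValueError(f"reference index {ref_idx} out of range")
    else:
        raise ValueError(f"unknown reference policy {reference!r}")

    b = vectors[ref_idx]
    values = np.array([descriptor_distance(v, b) for v in vectors])
    times = np.arange(len(vectors)) / frame_rate
    return ContractionRecord(times=times, values=values, reference_frame=ref_idx)


def _half_max_crossing(values: np.ndarray, peak: int, level: float) -> float:
    """Position of the last upstroke crossing of ``level`` before ``peak``."""
    i = peak
    while i > 0 and values[i - 1] > level:
        i -= 1
    if i == 0 or values[i] == values[i - 1]:
        return float(i)
    # linear interpolation between samples i-1 and i
    frac = (level - values[i - 1]) / (values[i] - values[i - 1])
    return (i - 1) + float(np.clip(frac, 0.0, 1.0))


def analyze_twitches(
    rec: ContractionRecord,
    min_prominence: float = 0.3,
    window_fraction: float = 0.8,
) -> ContractionRecord:
    """Detect twitch peaks, average aligned transients, normalize the trace.

    Peaks must rise above ``min_prominence`` × (trace range). Each twitch
    window has a fixed length of ``window_fraction`` × the median inter-peak
    interval and is centered on the upstroke half-maximum crossing of its
    peak; windows extending past the trace ends are dropped from the
    average. ``normalized`` maps the trace to [0, 1] by its range.
    """
    values = rec.values
    rng = float(values.max() - values.min())
    if rng <= 0:
        raise NoTwitchError("flat trace: no twitches to analyze")
    peaks, _ = find_peaks(values, prominence=min_prominence * rng)
    if len(peaks) == 0:
        raise NoTwitchError("no peak above the prominence threshold")

    normalized = (values - values.min()) / rng

    mean_transient = None
    if len(peaks) >= 2:
        period = float(np.median(np.diff(peaks)))
        win = max(int(round(window_fraction * period)), 3)
        vmin = float(values.min())
        windows = []
        for p in peaks:
            level = vmin + 0.5 * (values[p] - vmin)
            center = int(round(_half_max_crossing(values, int(p), level)))
            start = center - win // 2
            if start >= 0 and start + win <= len(values):
                windows.append(values[start : start + win])
        if windows:
            mean_transient = np.mean(windows, axis=0)

    return replace(
        rec,
        normalized=normalized,
        twitch_peaks=np.asarray(peaks),
        mean_transient=mean_transient,
    )


def raster_line_length(
    frame: np.ndarray, row: int, threshold: float = 0.5
) -> float:
    """Cell extent along one row by threshold crossings (dark cell).

    Scans the row left to right: the left edge is the first sub-threshold
    crossing, the right edge the last, both with sub-pixel linear
    interpolation; returns right − left in pixels.
    """
    frame = np.asarray(frame)
    if not 0 <= row < frame.shape[0]:
        raise ValueError(f"row {row} outside frame of height {frame.shape[0]}")
    profile = frame[row].astype(np.float64)
    below = profile < threshold
    if not below.any():
        raise NoEdgeError(f"no intensity below threshold {threshold} on row {row}")
    first = int(np.argmax(below))
    last = int(len(below) - 1 - np.argmax(below[::-1]))
    left = float(first)
    if first > 0:
        left = (first - 1) + (profile[first - 1] - threshold) / (
            profile[first - 1] - profile[first]
        )
    right = float(last)
    if last < len(profile) - 1:
        right = last + (profile[last] - threshold) / (
            profile[last] - profile[last + 1]
        )
    return right - left


def raster_line_trace(
    frames: Sequence[np.ndarray],
    row: int | None = None,
    threshold: float = 0.5,
    frame_rate: float = 30.0,
) -> RasterLineRecord:
    """Raster-line baseline over a whole sequence (row defaults to center)."""
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    if row is None:
        row = frames[0].shape[0] // 2
    lengths = np.array([raster_line_length(f, row, threshold) for f in frames])
    times = np.arange(len(frames)) / frame_rate
    return RasterLineRecord(times=times, lengths=lengths, row=row, threshold=threshold)
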