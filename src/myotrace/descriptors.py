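"""Fourier shape descriptors with selective invariances.

Two boundary signatures are supported:

* **complex-coords** — q(n) = x(n) + j·y(n), the boundary as a complex
  function of vertex index;
* **centroid-distance** — r(n) = ‖p(n) − (x_c, y_c)‖, the distance of each
  boundary point from the vertex-average centroid. Being real, its spectrum
  is conjugate-symmetric, so only N/2 frequencies are distinct; being a
  distance from the shape's own centroid, it is translation-invariant by
  construction.

The descriptors are the normalized DFT coefficients
Q(k) = (1/N) Σ q(n) e^{−j2πkn/N}. Normalization makes them invariant to
translation (Q(0) := 0 for complex-coords), starting point (subtract the
phase of Q(1), weighted by k) and rotation (take magnitudes), while
**deliberately keeping scale**: a contraction must register as a descriptor
change, so the magnitudes scale linearly with the shape.

Default truncation keeps the first K = 30 descriptors — the low-frequency
coefficients carry the gross shape, higher ones only boundary detail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .contour import ClosedContour
from .errors import PhaseReferenceWarning

Method = Literal["complex-coords", "centroid-distance"]

METHODS = ("complex-coords", "centroid-distance")

DEFAULT_K = 30


def _check_method(method: str) -> None:
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")


def _is_pow2(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass
class ShapeSignature:
    """1-D boundary signature of one contour (complex q(n) or real r(n))."""

    values: np.ndarray
    method: str
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        _check_method(self.method)
        if not _is_pow2(len(self.values)):
            raise ValueError(
                f"signature length {len(self.values)} is not a power of two; "
                "resample the contour first"
            )


@dataclass
class DescriptorVector:
    """K non-negative descriptor magnitudes |Q(k)| for one frame.

    For complex-coords the translation slot Q(0) is excluded and the vector
    holds k = 1 … K; for centroid-distance the DC term (mean radius — genuine
    size information) is retained and the vector holds k = 0 … K−1.
    """

    magnitudes: np.ndarray
    method: str
    frame_index: int = 0

    def __post_init__(self) -> None:
        _check_method(self.method)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if np.any(self.magnitudes < 0):
            raise ValueError("descriptor magnitudes must be non-negative")

    @property
    def K(self) -> int:
        return len(self.magnitudes)

    def norm(self) -> float:
        return float(np.linalg.norm(self.magnitudes))


def make_signature(c: ClosedContour, method: str = "centroid-distance") -> ShapeSignature:
    """Build the boundary signature of a resampled contour."""
    _check_method(method)
    if not _is_pow2(len(c)):
        raise ValueError(
            f"contour has {len(c)} vertices, not a power of two; "
            "apply resample_contour first"
        )
    xc, yc = c.centroid()
    if method == "complex-coords":
        values = c.x + 1j * c.y
    else:
        values = np.hypot(c.x - xc, c.y - yc)
    return ShapeSignature(values=values, method=method, centroid=(xc, yc))


def fourier_transform(s: ShapeSignature | np.ndarray) -> np.ndarray:
    """Normalized DFT Q(k) = (1/N) Σ_n q(n) e^{−j2πkn/N}, k = 0 … N−1."""
    values = s.values if isinstance(s, ShapeSignature) else np.asarray(s)
    n = len(values)
    if not _is_pow2(n):
        raise ValueError(f"signature length {n} is not a power of two")
    return np.fft.fft(values) / n


def dft_direct(values: np.ndarray) -> np.ndarray:
    """Direct O(N²) evaluation of the normalized DFT (reference/oracle)."""
    values = np.asarray(values)
    n = len(values)
    k = np.arange(n)
    w = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return (w @ values.astype(complex)) / n


def normalize_descriptors(
    Q: np.ndarray,
    method: str = "centroid-distance",
    K: int = DEFAULT_K,
    frame_index: int = 0,
) -> DescriptorVector:
    """Apply the invariance normalizations and truncate to K magnitudes.

    Steps, in order:

    1. translation — complex-coords only: Q(0) := 0 (the DC term is the
       centroid);
    2. starting point — multiply Q(k) by e^{−jφ₁k}, φ₁ = arg Q(1) via the
       two-argument arctangent; if Q(1) vanishes exactly (perfectly
       symmetric shape) the phase reference falls back to the lowest nonzero
       coefficient, with a :class:`PhaseReferenceWarning`;
    3. rotation — take |Q(k)|;
    4. truncation — keep k = 1 … K (complex-coords) or k = 0 … K−1
       (centroid-distance, which only has N/2 distinct frequencies).

    Scale is deliberately not normalized: magnitudes are linear in uniform
    scaling of the contour, which is what lets the descriptors register a
    contraction.
    """
    _check_method(method)
    Q = np.asarray(Q, dtype=complex).copy()
    n = len(Q)
    if K < 1:
        raise ValueError("K must be >= 1")
    if method == "centroid-distance" and K > n // 2:
        raise ValueError(
            f"K={K} exceeds the N/2={n // 2} distinct frequencies of a real signature"
        )
    if method == "complex-coords" and K > n - 1:
        raise ValueError(f"K={K} exceeds the N-1={n - 1} available frequencies")

    if method == "complex-coords":
        Q[0] = 0.0

    if Q[1] != 0:
        phi1 = float(np.angle(Q[1]))
    else:
        nonzero = np.flatnonzero(Q[1:]) + 1
        if len(nonzero) == 0:
            phi1 = 0.0
        else:
            phi1 = float(np.angle(Q[nonzero[0]]))
        warnings.warn(
            "Q(1) = 0; phase reference fell back to the lowest nonzero coefficient",
            PhaseReferenceWarning,
            stacklevel=2,
        )
    Q = Q * np.exp(-1j * phi1 * np.arange(n))
    mags = np.abs(Q)

    if method == "complex-coords":
        kept = mags[1 : K + 1]
    else:
        kept = mags[:K]
    return DescriptorVector(magnitudes=kept, method=method, frame_index=frame_index)


def describe_contour(
    c: ClosedContour, method: str = "centroid-distance", K: int = DEFAULT_K
) -> DescriptorVector:
    """Signature → transform → normalization, in one call."""
    sig = make_signature(c, method)
    return normalize_descriptors(
        fourier_transform(sig), method, K, frame_index=c.frame_index
    )


def reconstruct_signature(Q: np.ndarray, K: int) -> np.ndarray:
    """Inverse DFT keeping only the K lowest |frequency| bins (plus DC).

    Used to study how much boundary information the low-frequency
    descriptors retain.
    """
    Q = np.asarray(Q, dtype=complex)
    n = len(Q)
    keep = np.zeros(n, dtype=complex)
    keep[0] = Q[0]
    for k in range(1, min(K, n // 2) + 1):
        keep[k] = Q[k]
        keep[-k] = Q[-k]
    return np.fft.ifft(keep) * n
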