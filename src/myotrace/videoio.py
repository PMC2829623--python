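"""Reading and writing frame sequences and contraction traces.

The canonical in-memory representation is :class:`FrameSequence`: a list of
2-D float arrays with intensities in [0, 1], pixel centers at integer
coordinates, ``x`` = column, ``y`` = row, origin at the top-left, 0-based.
Integer inputs are normalized by the maximum of their bit depth (255 for
8-bit, 65535 for 16-bit); float inputs are expected to already lie in
[0, 1] and pass through unchanged, so normalization is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import EmptySequenceError, MixedFrameSizeError, UnsupportedFormatError

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}

# Luminance weights for Rec. 709 primaries (same convention as rgb2gray).
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class FrameSequence:
    """Ordered grayscale frames plus acquisition metadata.

    Parameters
    ----------
    frames : list of 2-D float arrays
        Intensities in [0, 1]; all frames share one shape.
    frame_rate : float
        Acquisition rate in frames per second.
    pixel_size : float, optional
        Micrometers per pixel, if known.
    source : str
        Provenance string (path or generator description).
    """

    frames: list[np.ndarray]
    frame_rate: float = 30.0
    pixel_size: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise EmptySequenceError("a FrameSequence needs at least one frame")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D (shape {f.shape})")
            if f.shape != shape:
                raise MixedFrameSizeError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )
        lo = min(float(f.min()) for f in self.frames)
        hi = max(float(f.max()) for f in self.frames)
        if lo < 0.0 or hi > 1.0 + 1e-9:
            raise ValueError(f"intensities outside [0, 1]: range [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return np.arange(len(self.frames)) / self.frame_rate

    def as_array(self) -> np.ndarray:
        return np.stack(self.frames, axis=0)


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically: frame_2 < frame_10."""
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in re.split(r"(\d+)", name)
    )


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Convert one frame to grayscale float64 in [0, 1]."""
    a = np.asarray(arr)
    if a.ndim == 3:  # color -> luminance
        a = a[..., :3].astype(np.float64) @ _LUMA
        if np.issubdtype(np.asarray(arr).dtype, np.integer):
            a = a / np.iinfo(np.asarray(arr).dtype).max
        return np.clip(a, 0.0, 1.0)
    if np.issubdtype(a.dtype, np.integer):
        return a.astype(np.float64) / np.iinfo(a.dtype).max
    a = a.astype(np.float64)
    if a.size and (a.min() < 0 or a.max() > 1.0 + 1e-9):
        raise ValueError("float frames must already be scaled to [0, 1]")
    return a


def load_frames(
    path: str | Path,
    frame_rate_override: float | None = None,
    pixel_size: float | None = None,
) -> FrameSequence:
    """Load a frame sequence from a TIFF stack, AVI file, or image directory.

    Directory entries are ordered by natural sort of their filenames, so
    ``frame_2.png`` precedes ``frame_10.png``. All intensities come back
    normalized to [0, 1] by the source bit depth; color frames are reduced
    to luminance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")

    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise EmptySequenceError(f"no image files in directory {path}")
        raw = [iio.imread(f) for f in files]
    elif path.suffix.lower() in {".tif", ".tiff"}:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        raw = list(stack)
    elif path.suffix.lower() == ".avi":
        try:
            import imageio.v3 as iio

            raw = list(iio.imiter(path))
        except Exception as exc:  # plugin missing or broken container
            raise UnsupportedFormatError(
                f"cannot decode AVI {path}: {exc}; install an ffmpeg-capable "
                "imageio plugin or convert the recording to a TIFF stack"
            ) from exc
        if not raw:
            raise EmptySequenceError(f"AVI {path} contains no frames")
    else:
        raise UnsupportedFormatError(f"unrecognized container: {path.suffix!r}")

    frames = [_to_unit_float(a) for a in raw]
    return FrameSequence(
        frames=frames,
        frame_rate=frame_rate_override if frame_rate_override else 30.0,
        pixel_size=pixel_size,
        source=str(path),
    )


def save_frames(seq: FrameSequence, path: str | Path, dtype: str = "uint8") -> Path:
    """Write a sequence as a multi-page TIFF stack.

    ``dtype`` of ``uint8``/``uint16`` quantizes by the bit-depth maximum
    (the inverse of the load normalization); ``float32`` is lossless to
    single precision.
    """
    path = Path(path)
    stack = seq.as_array()
    if dtype == "uint8":
        data = np.rint(stack * 255).astype(np.uint8)
    elif dtype == "uint16":
        data = np.rint(stack * 65535).astype(np.uint16)
    elif dtype == "float32":
        data = stack.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, data)
    return path


def write_trace(record, path: str | Path) -> Path:
    """Write a contraction record as a CSV table, one row per frame.

    Columns: frame index, time in seconds, contraction value (percent
    descriptor distance from the reference frame), and the range-normalized
    value if present. Floats are written with full ``repr`` precision so the
    table reads back losslessly.
    """
    if len(record.values) == 0:
        raise EmptySequenceError("cannot write an empty contraction record")
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(record.values)),
            "time_s": record.times,
            "contraction_value": record.values,
            "normalized_value": (
                record.normalized
                if record.normalized is not None
                else np.full(len(record.values), np.nan)
            ),
        }
    )
    df.to_csv(path, index=False)  # default repr is shortest round-trip
    return path


def read_trace(path: str | Path) -> pd.DataFrame:
    """Read back a trace CSV written by :func:`write_trace`."""
    return pd.read_csv(path, float_precision="round_trip")
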