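"""Two-class segmentation of smoothed bright-field frames.

An isolated rod-shaped myocyte under bright-field illumination appears as a
dark body on a bright background, so a global two-class threshold (Otsu's
between-class variance maximization) separates cell from background once the
frame has been TV-smoothed. Morphological cleanup then enforces the contract
the contour stage relies on: exactly one hole-free foreground component.

Polarity handling is exact: a ``bright-cell`` frame is negated internally
and segmented with the dark-cell logic, so inverting the intensities and
flipping the flag yields the identical mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing

from .errors import CellClippedWarning, NoCellError


@dataclass
class SegmentationMask:
    """Binary cell/background labeling of one frame (True = cell).

    ``threshold`` and ``polarity`` record how the mask was obtained, so the
    contour stage can re-localize the boundary at sub-pixel accuracy on the
    intensity image the mask came from.
    """

    mask: np.ndarray
    frame_index: int = 0
    threshold: float | None = None
    polarity: str = "dark-cell"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise NoCellError("mask has empty foreground")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = label(mask, connectivity=2)
    props = regionprops(labels)
    if not props:
        raise NoCellError("no connected component in mask")
    center = (np.array(mask.shape) - 1) / 2.0
    # Largest area; ties broken by centroid proximity to the frame center.
    best = min(
        props,
        key=lambda p: (-p.area, float(np.hypot(*(np.array(p.centroid) - center)))),
    )
    return labels == best.label


def segment_frame(
    u: np.ndarray, polarity: str = "dark-cell", frame_index: int = 0
) -> SegmentationMask:
    """Segment one smoothed frame into a single-cell binary mask.

    Parameters
    ----------
    u : 2-D array in [0, 1]
    polarity : {"dark-cell", "bright-cell"}
        Side of the threshold the cell lies on.

    Raises
    ------
    NoCellError
        If thresholding leaves no foreground (e.g. a uniform frame).

    Warns
    -----
    CellClippedWarning
        If the foreground touches three or more image borders.
    """
    u = np.asarray(u, dtype=np.float64)
    if polarity == "dark-cell":
        v = u
    elif polarity == "bright-cell":
        v = -u
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    if float(v.max()) == float(v.min()):
        raise NoCellError("uniform frame: no threshold separates cell from background")
    t = threshold_otsu(v)
    raw = v < t
    if not raw.any():
        raise NoCellError("no pixel below the automatic threshold")

    cleaned = closing(raw, np.ones((3, 3), dtype=bool))
    cleaned = binary_fill_holes(cleaned)
    mask = _largest_component(cleaned)

    touched = sum(
        (int(mask[0, :].any()), int(mask[-1, :].any()),
         int(mask[:, 0].any()), int(mask[:, -1].any()))
    )
    if touched >= 3:
        warnings.warn(
            f"cell touches {touched} image borders; the contour is clipped",
            CellClippedWarning,
            stacklevel=2,
        )
    return SegmentationMask(
        mask=mask, frame_index=frame_index, threshold=float(t), polarity=polarity
    )
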