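"""Named failure modes shared across the pipeline stages.

Every stage raises a distinct exception type so that pipeline-level error
reporting can identify which stage rejected the data and why.
"""


class MyotraceError(Exception):
    """Base class for all myotrace failures."""


class EmptySequenceError(MyotraceError):
    """A frame source contained zero frames."""


class MixedFrameSizeError(MyotraceError):
    """Frames in one sequence do not share identical dimensions."""


class UnsupportedFormatError(MyotraceError):
    """The input container format cannot be decoded."""


class NoCellError(MyotraceError):
    """Segmentation found no foreground after thresholding."""


class DegenerateContourError(MyotraceError):
    """A mask component yields too few boundary vertices for a contour."""


class ZeroPerimeterError(MyotraceError):
    """A contour has zero total arclength and cannot be resampled."""


class ZeroNormError(MyotraceError):
    """The reference descriptor vector has zero norm."""


class NoEdgeError(MyotraceError):
    """A raster line found no threshold crossing (no cell on the row)."""


class NoTwitchError(MyotraceError):
    """Peak detection found no twitch in a contraction trace."""


class FrameOverflowError(MyotraceError):
    """The simulated cell leaves the frame after motion is applied."""


class ConfigError(MyotraceError):
    """A pipeline configuration failed validation."""


class CellClippedWarning(UserWarning):
    """The segmented cell touches three or more image borders."""


class PhaseReferenceWarning(UserWarning):
    """Q(1) vanished; the phase reference fell back to the lowest nonzero
    coefficient."""
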