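"""Exception hierarchy for pmnshape.

All errors derive from :class:`PmnShapeError` so callers can catch the
package's failures with a single except clause; the measure battery relies
on this to capture per-measure failures instead of aborting a cell.
"""


class PmnShapeError(Exception):
    """Base class for all pmnshape errors."""


class EmptyForegroundError(PmnShapeError):
    """No pixel passed the threshold: there is no cell in the frame."""


class BorderTouchError(PmnShapeError):
    """The silhouette touches the image border, so perimeter/area counts
    would be truncated."""


class FrameError(PmnShapeError):
    """A per-frame failure inside a movie, annotated with the frame index."""

    def __init__(self, frame_index: int, cause: Exception):
        self.frame_index = frame_index
        self.cause = cause
        super().__init__(f"frame {frame_index}: {cause}")


class DegenerateSeriesError(PmnShapeError):
    """Zero-variance series: skewness/kurtosis are undefined."""


class SeriesTooShortError(PmnShapeError):
    """The series is too short for the requested embedding or estimate."""


class InsufficientBinsError(PmnShapeError):
    """Too few usable spectral bins for the log-log slope fit."""


class NoQualifyingPeakError(PmnShapeError):
    """No spectral local maximum exceeds the qualifying power threshold."""


class NoValidNeighborError(PmnShapeError):
    """Neighbour replacement failed too often in the Wolf algorithm."""


class StarConvexityError(PmnShapeError):
    """The radial shape model left the star-convex regime (r(theta) ~ 0)."""


class GridError(PmnShapeError):
    """A shape does not fit on (or is centred off) the raster grid."""


class InsufficientGroupError(PmnShapeError):
    """A group is too small for the two-sample comparison."""
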