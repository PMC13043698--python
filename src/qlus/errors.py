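"""Exception hierarchy shared across the pipeline.

Every failure mode the pipeline can surface deliberately (as opposed to a
programming error) derives from :class:`QlusError`, so callers can catch one
base class at the CLI boundary.
"""


class QlusError(Exception):
    """Base class for all deliberate pipeline errors."""


class UnsupportedFormatError(QlusError):
    """Image is not a single-frame monochrome DICOM/PNG."""


class MissingMetadataError(QlusError):
    """Required acquisition metadata (subject, zone) absent and not overridden."""


class RoiSpecError(QlusError):
    """ROI specification violates its own invariants."""


class OutOfFrameError(RoiSpecError):
    """ROI band does not fit inside the image (truncation is never silent)."""


class DegenerateRoiError(QlusError):
    """Rasterised ROI has too few pixels to yield stable statistics."""


class NoPairsError(QlusError):
    """No pixel pair has both endpoints inside the mask at the given offset."""


class ShapeError(QlusError):
    """Array shapes are incompatible (mask vs frame, x vs y)."""


class ValidationError(QlusError):
    """A clinical record or domain value violates its invariants."""


class DegenerateInputError(QlusError):
    """Statistical input is constant or too small for the requested estimate."""


class IncompleteSubjectError(QlusError):
    """Fewer imaged zones than the aggregation policy requires."""


class GeometryError(QlusError):
    """Simulation geometry cannot accommodate pleural band plus ROI depth."""
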