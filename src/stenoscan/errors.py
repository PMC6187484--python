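"""Exception hierarchy shared across the pipeline stages."""


class StenoscanError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(StenoscanError, ValueError):
    """An argument is outside its documented domain."""


class OutOfRangeError(StenoscanError, ValueError):
    """A position or index lies outside the valid extent."""


class DegenerateGeometryError(StenoscanError, ValueError):
    """Geometric construction is ill-posed (e.g. collinear circle points)."""


class DegenerateContourError(StenoscanError, RuntimeError):
    """A contour collapsed below a usable vertex count during evolution."""


class SegmentationInconsistencyError(StenoscanError, RuntimeError):
    """Lumen and vessel contours violate their nesting contract."""


class InsufficientDataError(StenoscanError, ValueError):
    """Not enough frames/slices to perform the requested reconstruction."""


class PropagationError(StenoscanError, RuntimeError):
    """Sequential segmentation failed on a specific frame.

    Attributes
    ----------
    frame_index : int
        Index of the frame on which propagation failed.
    partial : list
        Per-frame results successfully computed before the failure.
    """

    def __init__(self, frame_index, partial, cause):
        super().__init__(
            f"contour propagation failed on frame {frame_index}: {cause}"
        )
        self.frame_index = frame_index
        self.partial = partial
        self.cause = cause


class PipelineStageError(StenoscanError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
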