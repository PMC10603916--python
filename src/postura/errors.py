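"""Exception hierarchy for the posture-assessment pipeline.

Every stage raises a subclass of :class:`PosturaError`, so callers can
distinguish expected domain failures (a missing plumb line, an implausible
marker configuration) from programming errors.
"""


class PosturaError(Exception):
    """Base class for all domain errors raised by this package."""


class SceneSpecError(PosturaError):
    """A synthetic scene specification is invalid or unrenderable."""


class DetectionError(PosturaError):
    """Base class for detection-stage failures."""


class ScaleNotFoundError(DetectionError):
    """No component in the image qualifies as the scale rectangle."""


class AmbiguousScaleError(DetectionError):
    """More than one component is an equally plausible scale rectangle."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "ambiguous scale reference: %d equally plausible components "
            "(areas %s)" % (len(self.candidates),
                            [round(c, 1) for c in self.candidates])
        )


class PlumbLineNotFoundError(DetectionError):
    """No sufficiently elongated component of the string color exists.

    This is the failure mode of a red plumb string photographed against a
    red background: the color threshold merges string and wall into one
    blob that no longer looks like a line.
    """


class CalibrationError(PosturaError):
    """Calibration could not be completed (a reference is missing)."""


class LandmarkError(PosturaError):
    """Base class for blob-to-site assignment failures."""


class InsufficientMarkersError(LandmarkError):
    """Fewer blobs were detected than are needed to attempt assignment."""


class ImplausibleConfigurationError(LandmarkError):
    """The best blob-to-site assignment is too distorted to trust."""


class DegenerateSampleError(PosturaError):
    """A statistical routine received a sample it cannot process
    (zero variance, no nonzero differences, too few points)."""


class MismatchedTablesError(PosturaError):
    """Two feature tables to be compared do not share subjects/features."""

    def __init__(self, message, detail=None):
        self.detail = detail or {}
        super().__init__(message)


class StratificationError(PosturaError):
    """An evaluation partition lost a class from its training portion."""


class SchemeDegradationError(PosturaError):
    """The requested evaluation scheme is infeasible for the data size."""


class ViewProcessingError(PosturaError):
    """A pipeline stage failed while processing one photographic view."""

    def __init__(self, view, stage, original, hint=None):
        self.view = view
        self.stage = stage
        self.original = original
        self.hint = hint
        msg = f"[{view}/{stage}] {original}"
        if hint:
            msg += f" (hint: {hint})"
        super().__init__(msg)
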