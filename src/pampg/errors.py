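"""Exception and warning types shared across the package."""


class PampgError(Exception):
    """Base class for all pampg errors."""


class InvalidConfigError(PampgError, ValueError):
    """A configuration value violates its documented invariant."""


class AliasingError(InvalidConfigError):
    """A requested frequency is at or above the Nyquist limit of its channel."""


class OutOfFieldError(PampgError, ValueError):
    """A simulated vessel leaves the imaging grid at a displacement extreme."""


class ROIError(PampgError, ValueError):
    """A region of interest is empty or not contained in the frame."""


class TrackingLostError(PampgError, RuntimeError):
    """The tracking ROI was clamped fully out of the field of view.

    Carries ``frame_index`` of the frame on which tracking failed.
    """

    def __init__(self, message: str, frame_index: int):
        super().__init__(message)
        self.frame_index = frame_index


class AlignmentError(PampgError, ValueError):
    """Two channels cannot be placed on a common time base."""


class InsufficientLengthError(PampgError, ValueError):
    """A trace is too short for the requested filtering or analysis."""


class NonUniformSamplingError(PampgError, ValueError):
    """Spectral analysis requires uniformly sampled input."""


class InsufficientStatisticsError(PampgError, RuntimeError):
    """Too few detected photons to form the requested tally.

    Carries ``n_detected``, the number of detected photon packets.
    """

    def __init__(self, message: str, n_detected: int = 0):
        super().__init__(message)
        self.n_detected = n_detected


class UndefinedPhaseError(PampgError, RuntimeError):
    """Phase lag is undefined because a channel is not pulsatile."""


class StageError(PampgError, RuntimeError):
    """A pipeline stage failed; carries ``stage``, the failing stage's name."""

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage


class MetadataError(PampgError, ValueError):
    """A required metadata key is missing from a sidecar file."""


class DegenerateROIWarning(UserWarning):
    """The ROI is flat (all pixels equal); the argmax is its origin."""


class ShortRecordWarning(UserWarning):
    """The record is shorter than the recommended analysis minimum (10 s)."""
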