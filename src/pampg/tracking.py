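"""Vessel tracking by per-frame maximum-pixel localization.

The tracker reproduces the published algorithm: select an ROI containing a
single vessel, find the pixel with the maximum PA amplitude, repeat on each
consecutive frame, and read off the pixel's axial position.  Localization
is integer-pixel by default (the algorithm tracks *the pixel*); an optional
three-point parabolic sub-pixel refinement is available behind a flag.  The
ROI follows the vessel by default: before each search it is re-centred on
the previous frame's maximum (clamped to the frame bounds), which keeps a
slowly drifting vessel in view.  A fixed-ROI mode reproduces the strictly
literal single-ROI reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateROIWarning,
    InvalidConfigError,
    ROIError,
    TrackingLostError,
)

#: Default ROI size (axial × lateral pixels): ≈100 µm × 160 µm at the
#: default pitches, comfortably containing one vessel cross-section.
DEFAULT_ROI_SHAPE = (64, 32)


@dataclass(frozen=True)
class FrameStack:
    """Time-ordered B-mode frames with pixel pitches and timestamps."""

    data: np.ndarray  # (time, axial, lateral), a.u.
    axial_pitch_um: float
    lateral_pitch_um: float
    timestamps: np.ndarray  # s, one per frame

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise InvalidConfigError("frame stack must be (time, axial, lateral)")
        if len(self.timestamps) != self.data.shape[0]:
            raise InvalidConfigError("one timestamp per frame required")
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise InvalidConfigError("pixel pitches must be > 0")
        if np.any(np.diff(self.timestamps) <= 0):
            raise InvalidConfigError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass(frozen=True)
class VesselROI:
    """Half-open pixel rectangle [axial_start, axial_stop) × [lateral_start, lateral_stop)."""

    axial_start: int
    axial_stop: int
    lateral_start: int
    lateral_stop: int
    vessel_id: int = 0

    def __post_init__(self) -> None:
        if self.axial_stop <= self.axial_start or self.lateral_stop <= self.lateral_start:
            raise ROIError("ROI must be nonempty")
        if self.axial_start < 0 or self.lateral_start < 0:
            raise ROIError("ROI must have nonnegative origin")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.axial_stop - self.axial_start,
                self.lateral_stop - self.lateral_start)

    @classmethod
    def centered(cls, axial_center: int, lateral_center: int,
                 shape: tuple[int, int] = DEFAULT_ROI_SHAPE,
                 bounds: tuple[int, int] | None = None,
                 vessel_id: int = 0) -> "VesselROI":
        """ROI of the given shape centred on a pixel, clamped into ``bounds``."""
        na, nl = shape
        a0 = axial_center - na // 2
        l0 = lateral_center - nl // 2
        if bounds is not None:
            a0 = min(max(a0, 0), max(bounds[0] - na, 0))
            l0 = min(max(l0, 0), max(bounds[1] - nl, 0))
        else:
            a0, l0 = max(a0, 0), max(l0, 0)
        return cls(a0, a0 + na, l0, l0 + nl, vessel_id=vessel_id)


@dataclass(frozen=True)
class VesselTrack:
    """Per-frame axial position of one tracked vessel."""

    vessel_id: int
    pixel_positions: np.ndarray  # axial pixel index (float if sub-pixel)
    positions_um: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.pixel_positions) == len(self.positions_um)
                == len(self.timestamps)):
            raise InvalidConfigError("track arrays must have equal length")


@dataclass(frozen=True)
class MotionTrace:
    """Averaged, de-meaned vascular motion (µm vs s)."""

    timestamps: np.ndarray
    positions_um: np.ndarray

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


def _check_roi(frame_shape: tuple[int, int], roi: VesselROI) -> None:
    na, nl = frame_shape
    if roi.axial_stop > na or roi.lateral_stop > nl:
        raise ROIError(
            f"ROI {roi} exceeds frame bounds {frame_shape}"
        )


def find_max_pixel(frame: np.ndarray, roi: VesselROI) -> tuple[int, int]:
    """Coordinates (axial, lateral) of the maximum intensity inside the ROI.

    Ties break toward the smallest axial index, then the smallest lateral
    index (C-order argmax).  A flat ROI returns the ROI origin and emits a
    :class:`DegenerateROIWarning`.
    """
    if frame.ndim != 2:
        raise ROIError("frame must be 2-D (axial, lateral)")
    _check_roi(frame.shape, roi)
    sub = frame[roi.axial_start:roi.axial_stop, roi.lateral_start:roi.lateral_stop]
    if sub.size == 0:
        raise ROIError("empty ROI")
    if np.all(sub == sub.flat[0]):
        warnings.warn("flat ROI: returning ROI origin", DegenerateROIWarning,
                      stacklevel=2)
        return roi.axial_start, roi.lateral_start
    ia, il = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return roi.axial_start + int(ia), roi.lateral_start + int(il)


def _parabolic_refine(col: np.ndarray, i: int) -> float:
    """Three-point parabolic interpolation of an axial peak index."""
    if i <= 0 or i >= len(col) - 1:
        return float(i)
    y0, y1, y2 = col[i - 1], col[i], col[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(i)
    return i + 0.5 * float((y0 - y2) / denom)


def track_vessel(stack: FrameStack, initial_roi: VesselROI,
                 recenter: bool = True, subpixel: bool = False) -> VesselTrack:
    """Track one vessel through all frames of the stack.

    Raises :class:`TrackingLostError` (carrying the frame index) if ROI
    re-centring clamps the ROI fully outside the field.
    """
    if stack.n_frames < 2:
        raise InvalidConfigError("tracking requires at least 2 frames")
    _check_roi(stack.shape, initial_roi)
    na, nl = stack.shape
    roi = initial_roi
    pix = np.empty(stack.n_frames)
    for k in range(stack.n_frames):
        frame = stack.data[k]
        try:
            ia, il = find_max_pixel(frame, roi)
        except ROIError as exc:
            raise TrackingLostError(
                f"ROI left the field of view at frame {k}", frame_index=k
            ) from exc
        if subpixel:
            pix[k] = _parabolic_refine(frame[:, il], ia)
        else:
            pix[k] = ia
        if recenter:
            roi = VesselROI.centered(ia, il, shape=roi.shape, bounds=(na, nl),
                                     vessel_id=roi.vessel_id)
    return VesselTrack(
        vessel_id=initial_roi.vessel_id,
        pixel_positions=pix,
        positions_um=pix * stack.axial_pitch_um,
        timestamps=np.asarray(stack.timestamps, dtype=float),
    )


def average_tracks(tracks: list[VesselTrack]) -> MotionTrace:
    """Pointwise mean of de-meaned tracks: the averaged vascular movement.

    Each track's own baseline depth (its mean) is subtracted first, so
    vessels at different depths contribute only their oscillation.
    """
    if not tracks:
        raise InvalidConfigError("at least one track required")
    t0 = tracks[0].timestamps
    for tr in tracks[1:]:
        if len(tr.timestamps) != len(t0) or not np.allclose(tr.timestamps, t0):
            raise AlignmentError("tracks have mismatched timestamps")
    demeaned = np.stack([tr.positions_um - tr.positions_um.mean() for tr in tracks])
    return MotionTrace(timestamps=t0.copy(), positions_um=demeaned.mean(axis=0))
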