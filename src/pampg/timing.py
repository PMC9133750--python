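"""Interleaved PAM/PPG timing schedule.

One hardware counter at the B-scan rate drives everything: the galvo
waveform and the PPG sample trigger fire on the counter edge (cycle start),
while the laser/PA acquisition is delayed by a quarter period so that the
B-scan is acquired during the forward half of the galvo sweep and the PPG
sample is taken during the reverse sweep.  Per cycle this yields exactly one
PA frame and one PPG sample that never overlap in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AcquisitionConfig
from .errors import InvalidConfigError


@dataclass(frozen=True)
class TimingSchedule:
    """Deterministic per-cycle timing of the two channels.

    ``pa_frame_timestamps`` are the centres of the PA acquisition windows
    (cycle start + T/2); ``ppg_sample_timestamps`` are the sampling instants
    (cycle start).  The fixed intra-cycle offset between the two channels is
    therefore T/2 − 0 = half a cycle (10 ms at 50 Hz) and is carried here as
    metadata for the cross-modal alignment stage.
    """

    cycle_period_s: float
    pa_window_start_offset_s: float
    pa_window_duration_s: float
    pa_frame_timestamps: np.ndarray
    ppg_sample_timestamps: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.ppg_sample_timestamps)

    @property
    def intra_cycle_offset_s(self) -> float:
        """PA frame timestamp minus PPG sample timestamp within one cycle."""
        return self.cycle_period_s / 2.0

    def pa_windows(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) arrays of the PA acquisition windows."""
        start = (self.pa_frame_timestamps
                 - self.pa_window_duration_s / 2.0)
        return start, start + self.pa_window_duration_s


def make_timing_schedule(config: AcquisitionConfig, duration_s: float) -> TimingSchedule:
    """Build the interleaved schedule covering ``duration_s`` of whole cycles.

    The PA window occupies the forward half-cycle [T/4, 3T/4) of each
    counter period; the PPG instant sits at the cycle start.  Raises
    :class:`InvalidConfigError` if the duration does not cover one cycle.
    """
    period = 1.0 / config.frame_rate_hz
    if duration_s <= 0:
        raise InvalidConfigError(f"duration must be positive, got {duration_s}")
    n = int(round(duration_s / period))
    if n < 1 or duration_s < period:
        raise InvalidConfigError(
            f"duration {duration_s} s is shorter than one cycle ({period} s)"
        )
    starts = np.arange(n) * period
    return TimingSchedule(
        cycle_period_s=period,
        pa_window_start_offset_s=period / 4.0,
        pa_window_duration_s=period / 2.0,
        pa_frame_timestamps=starts + period / 2.0,
        ppg_sample_timestamps=starts,
    )
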