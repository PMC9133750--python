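"""Cross-modal comparison of the PAM motion trace and the PPG trace.

The two channels are interleaved within each counter cycle (PA frame at
T/2, PPG sample at the cycle start), so their sample grids carry a fixed
half-cycle offset.  Alignment interpolates both channels, using their true
timestamps, onto one common uniform grid, which removes that offset
exactly.  On aligned channels the module quantifies the two headline
claims: the heart rates agree (dominant frequencies within one spectral
bin) and the channels are in phase (cross-correlation lag ≈ 0 once the PPG
reflectance polarity is flipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import BandConfig
from .errors import AlignmentError, InvalidConfigError, UndefinedPhaseError
from .spectral import Spectrum, is_pulsatile, power_spectrum
from .timing import TimingSchedule
from .tracking import MotionTrace
from .synthesis import PPGTrace, Trial


@dataclass(frozen=True)
class AlignedPair:
    """Two channels on a common uniform grid."""

    timestamps: np.ndarray
    motion: np.ndarray
    ppg: np.ndarray
    fs_hz: float


@dataclass(frozen=True)
class HRAgreement:
    """Dominant-frequency comparison between the two channels."""

    pam_freq_hz: float
    ppg_freq_hz: float
    pam_bpm: float
    ppg_bpm: float
    freq_difference_hz: float
    tolerance_hz: float
    agree: bool


@dataclass(frozen=True)
class PhaseResult:
    """Cross-correlation lag of PPG relative to PAM motion.

    Positive lag means the PPG waveform trails the vascular motion.
    """

    lag_s: float
    peak_correlation: float


@dataclass(frozen=True)
class TrialVerdict:
    """Channel-wise pulsatility decisions and the combined call."""

    motion_pulsatile: bool
    ppg_pulsatile: bool
    motion_prominence: float
    ppg_prominence: float
    verdict: str  # "normal" | "occluded" | "discordant"


def _as_time_series(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, MotionTrace):
        return trace.timestamps, trace.positions_um
    if isinstance(trace, PPGTrace):
        return trace.timestamps, trace.voltage_v
    t, v = trace
    return np.asarray(t, dtype=float), np.asarray(v, dtype=float)


def align_channels(motion, ppg, schedule: TimingSchedule | None = None,
                   fs_out_hz: float | None = None) -> AlignedPair:
    """Linearly interpolate both channels onto one uniform grid.

    The channels' true timestamps are used, so the deterministic
    intra-cycle offset between the PA window centre and the PPG sampling
    instant is removed by construction.  Raises :class:`AlignmentError` if
    the time ranges do not overlap by at least one sample.
    """
    tm, vm = _as_time_series(motion)
    tp, vp = _as_time_series(ppg)
    t0 = max(tm[0], tp[0])
    t1 = min(tm[-1], tp[-1])
    if t1 <= t0:
        raise AlignmentError(
            f"channels cover disjoint time ranges [{tm[0]}, {tm[-1]}] vs "
            f"[{tp[0]}, {tp[-1]}]"
        )
    if fs_out_hz is None:
        if schedule is not None:
            fs_out_hz = 1.0 / schedule.cycle_period_s
        else:
            fs_out_hz = 1.0 / float(np.median(np.diff(tp)))
    n = int(np.floor((t1 - t0) * fs_out_hz)) + 1
    grid = t0 + np.arange(n) / fs_out_hz
    return AlignedPair(
        timestamps=grid,
        motion=np.interp(grid, tm, vm),
        ppg=np.interp(grid, tp, vp),
        fs_hz=fs_out_hz,
    )


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x - x.mean())


def phase_lag(pair: AlignedPair, band: BandConfig = BandConfig(),
              flip_ppg: bool = True, check_pulsatile: bool = True) -> PhaseResult:
    """Lag of the PPG channel relative to vascular motion in the cardiac band.

    Both channels are band-passed to the search band; the PPG channel is
    sign-flipped by default (systolic volume increase lowers reflectance,
    while the vessel is displaced upward), then the normalized
    cross-correlation is maximized over ± one cardiac period.  Raises
    :class:`UndefinedPhaseError` if either channel is non-pulsatile.
    """
    m = _bandpass(pair.motion, pair.fs_hz, band.search_band_hz)
    p = _bandpass(pair.ppg, pair.fs_hz, band.search_band_hz)
    if flip_ppg:
        p = -p

    spec_m = power_spectrum(pair.motion - pair.motion.mean(), pair.fs_hz, band=band)
    if check_pulsatile:
        spec_p = power_spectrum(pair.ppg - pair.ppg.mean(), pair.fs_hz, band=band)
        ok_m, _ = is_pulsatile(spec_m, band)
        ok_p, _ = is_pulsatile(spec_p, band)
        if not (ok_m and ok_p):
            raise UndefinedPhaseError(
                f"phase undefined: pulsatile(motion)={ok_m}, pulsatile(ppg)={ok_p}"
            )
    period = 1.0 / spec_m.dominant_freq_hz
    max_lag = int(round(period * pair.fs_hz))

    m = (m - m.mean()) / (m.std() or 1.0)
    p = (p - p.mean()) / (p.std() or 1.0)
    n = len(m)
    # full cross-correlation c[k] = sum m[i] * p[i + k], k in [-max_lag, max_lag]
    full = sps.correlate(p, m, mode="full") / n
    lags = sps.correlation_lags(len(p), len(m), mode="full")
    keep = np.abs(lags) <= max_lag
    c, lg = full[keep], lags[keep]
    i = int(np.argmax(c))
    return PhaseResult(lag_s=float(lg[i] / pair.fs_hz),
                       peak_correlation=float(c[i]))


def compare_hr(motion_spectrum: Spectrum, ppg_spectrum: Spectrum,
               tolerance_hz: float | None = None) -> HRAgreement:
    """Compare dominant frequencies; agreement within one spectral bin by default."""
    if (len(motion_spectrum.freqs_hz) != len(ppg_spectrum.freqs_hz)
            or abs(motion_spectrum.df_hz - ppg_spectrum.df_hz)
            > 1e-9 * motion_spectrum.df_hz):
        raise InvalidConfigError("spectra must share one frequency grid")
    if tolerance_hz is None:
        tolerance_hz = motion_spectrum.df_hz
    diff = motion_spectrum.dominant_freq_hz - ppg_spectrum.dominant_freq_hz
    return HRAgreement(
        pam_freq_hz=motion_spectrum.dominant_freq_hz,
        ppg_freq_hz=ppg_spectrum.dominant_freq_hz,
        pam_bpm=motion_spectrum.bpm,
        ppg_bpm=ppg_spectrum.bpm,
        freq_difference_hz=float(diff),
        tolerance_hz=float(tolerance_hz),
        agree=bool(abs(diff) <= tolerance_hz * (1 + 1e-9)),
    )


def classify_trial(trial: Trial, band: BandConfig = BandConfig(),
                   motion: MotionTrace | None = None) -> TrialVerdict:
    """Channel-wise pulsatility decisions and the combined verdict.

    ``motion`` may be the already-tracked averaged motion trace; if absent,
    all scene vessels are tracked with default ROIs seeded at their
    configured positions (the manual-ROI-selection step).  The verdict is
    "occluded" iff both channels are non-pulsatile, "normal" iff both are
    pulsatile, and "discordant" otherwise — disagreement is surfaced, never
    resolved silently.
    """
    from .pipeline import track_all_vessels  # late import to avoid a cycle

    from .spectral import detrend_highpass

    if motion is None:
        tracks = track_all_vessels(trial)
        from .tracking import average_tracks
        motion = average_tracks(tracks)

    fs_m = motion.fs_hz
    hp_m = detrend_highpass(motion.positions_um, fs_m, band.highpass_cutoff_hz)
    spec_m = power_spectrum(hp_m, fs_m, band=band)

    fs_p = trial.ppg.fs_hz
    hp_p = detrend_highpass(trial.ppg.voltage_v, fs_p, band.highpass_cutoff_hz)
    spec_p = power_spectrum(hp_p, fs_p, band=band)

    ok_m, prom_m = is_pulsatile(spec_m, band)
    ok_p, prom_p = is_pulsatile(spec_p, band)
    if ok_m and ok_p:
        verdict = "normal"
    elif not ok_m and not ok_p:
        verdict = "occluded"
    else:
        verdict = "discordant"
    return TrialVerdict(
        motion_pulsatile=ok_m, ppg_pulsatile=ok_p,
        motion_prominence=prom_m, ppg_prominence=prom_p,
        verdict=verdict,
    )
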