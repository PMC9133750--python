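"""Frequency-domain heart-rate extraction from motion and PPG traces.

The chain is: zero-phase high-pass at 1 Hz (suppressing sub-1 Hz subject
motion), a tapered and zero-padded periodogram, and the in-band spectral
argmax interpreted as the cardiac fundamental (×60 → BPM).  A channel is
called pulsatile when its dominant in-band peak exceeds the median in-band
power by a calibrated factor; under arterial occlusion neither channel
shows such a peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import BandConfig
from .errors import (
    InsufficientLengthError,
    InvalidConfigError,
    NonUniformSamplingError,
    ShortRecordWarning,
)

#: Minimum record length (s) recommended for heart-rate analysis.
MIN_ANALYSIS_DURATION_S = 10.0


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum with its in-band dominant peak."""

    freqs_hz: np.ndarray
    power: np.ndarray
    dominant_freq_hz: float
    bpm: float
    prominence_ratio: float
    band_hz: tuple[float, float]
    fs_hz: float

    @property
    def df_hz(self) -> float:
        """Frequency grid spacing."""
        return float(self.freqs_hz[1] - self.freqs_hz[0])


def _check_uniform(times: np.ndarray) -> float:
    dt = np.diff(times)
    if len(dt) == 0 or np.any(dt <= 0):
        raise NonUniformSamplingError("need at least two increasing timestamps")
    if (dt.max() - dt.min()) > 1e-6 * dt.mean():
        raise NonUniformSamplingError(
            "timestamps are not uniform; resample before spectral analysis"
        )
    return 1.0 / float(dt.mean())


def highpass_sos(cutoff_hz: float, fs_hz: float, order: int = 8):
    """Zero-phase-ready Butterworth high-pass sections.

    The design corner sits at 0.85×cutoff so that, after forward–backward
    filtering, components at ≥1.2×cutoff lose <1 dB while those at ≤0.3×
    cutoff lose >40 dB.
    """
    wn = 0.85 * cutoff_hz / (fs_hz / 2.0)
    if not (0 < wn < 1):
        raise InvalidConfigError(
            f"cutoff {cutoff_hz} Hz invalid for sampling rate {fs_hz} Hz"
        )
    return sps.butter(order, wn, btype="highpass", output="sos")


def detrend_highpass(values: np.ndarray, fs_hz: float,
                     cutoff_hz: float = 1.0) -> np.ndarray:
    """Remove the mean and sub-cutoff drift, zero-phase.

    Raises :class:`InsufficientLengthError` if the record is shorter than
    one period of the cutoff frequency.
    """
    values = np.asarray(values, dtype=float)
    if len(values) / fs_hz < 1.0 / cutoff_hz:
        raise InsufficientLengthError(
            f"record of {len(values) / fs_hz:.2f} s is shorter than one "
            f"{cutoff_hz} Hz period"
        )
    sos = highpass_sos(cutoff_hz, fs_hz)
    return sps.sosfiltfilt(sos, values - values.mean())


def power_spectrum(values: np.ndarray, fs_hz: float | None = None,
                   times: np.ndarray | None = None,
                   band: BandConfig = BandConfig()) -> Spectrum:
    """Tapered, zero-padded periodogram with its in-band dominant peak.

    With a rectangular window and no padding the total power equals the
    time-domain mean-square (Parseval).  The zero-padding (×8 by default)
    refines the read-out grid to ≤(1/duration)/pad_factor.
    """
    values = np.asarray(values, dtype=float)
    if times is not None:
        fs_hz = _check_uniform(np.asarray(times, dtype=float))
    if fs_hz is None or fs_hz <= 0:
        raise InvalidConfigError("sampling rate required (fs_hz or times)")
    n = len(values)
    if n < 8:
        raise InsufficientLengthError("record too short for spectral analysis")
    if n / fs_hz < MIN_ANALYSIS_DURATION_S:
        warnings.warn(
            f"record of {n / fs_hz:.1f} s is below the recommended "
            f"{MIN_ANALYSIS_DURATION_S:.0f} s analysis minimum",
            ShortRecordWarning, stacklevel=2,
        )
    nfft = int(band.pad_factor) * n
    freqs, power = sps.periodogram(
        values, fs=fs_hz, window=band.window, nfft=nfft,
        detrend="constant", scaling="spectrum",
    )
    f_dom, bpm, prom = dominant_frequency((freqs, power), band.search_band_hz)
    return Spectrum(
        freqs_hz=freqs, power=power, dominant_freq_hz=f_dom, bpm=bpm,
        prominence_ratio=prom, band_hz=tuple(band.search_band_hz), fs_hz=fs_hz,
    )


def dominant_frequency(spectrum, band_hz: tuple[float, float]
                       ) -> tuple[float, float, float]:
    """(freq, BPM, prominence) of the in-band power argmax.

    ``spectrum`` is a :class:`Spectrum` or a (freqs, power) pair.  Ties
    break toward the lower frequency.  Prominence is peak power over the
    median in-band power.
    """
    if isinstance(spectrum, Spectrum):
        freqs, power = spectrum.freqs_hz, spectrum.power
    else:
        freqs, power = spectrum
    lo, hi = band_hz
    if not (0 <= lo < hi):
        raise InvalidConfigError("band must satisfy 0 <= low < high")
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise InvalidConfigError(
            f"band [{lo}, {hi}] Hz contains no grid frequencies"
        )
    p = power[mask]
    f = freqs[mask]
    i = int(np.argmax(p))  # first (= lowest-frequency) maximum
    med = float(np.median(p))
    prom = float(p[i] / med) if med > 0 else np.inf
    return float(f[i]), float(f[i]) * 60.0, prom


def peak_to_peak_amplitude(values: np.ndarray, robust: bool = True) -> float:
    """Peak-to-peak excursion of a (detrended) motion trace in its own units.

    The robust default uses the 98th−2nd percentile spread, insensitive to
    isolated tracking outliers; ``robust=False`` gives the plain max−min.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidConfigError("empty trace")
    if robust:
        hi, lo = np.percentile(values, [98.0, 2.0])
        return float(hi - lo)
    return float(values.max() - values.min())


def is_pulsatile(spectrum: Spectrum, band: BandConfig = BandConfig()
                 ) -> tuple[bool, float]:
    """Decide whether a channel carries a cardiac peak.

    True iff the dominant in-band peak power exceeds the median in-band
    power by at least ``band.pulsatility_threshold``.
    """
    _, _, prom = dominant_frequency(spectrum, band.search_band_hz)
    return bool(prom >= band.pulsatility_threshold), prom
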