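"""Cardiac driving waveform shared by the vascular-motion and PPG channels.

The pulse shape is a fundamental plus decaying harmonics — a generic
stand-in for an arterial pulse; the quantity the downstream analysis
recovers is the fundamental frequency, not the shape.  Heart-rate
variability is modelled as a slowly varying instantaneous frequency
(Gaussian control points at 1 s spacing, cosine-interpolated), integrated
into a phase so that both channels, which sample the same waveform at
different instants, stay coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AliasingError, InvalidConfigError


@dataclass(frozen=True)
class CardiacWaveform:
    """A unit peak-to-peak cardiac waveform evaluable at arbitrary times.

    ``samples`` holds the waveform on a uniform grid at ``rate_hz``; the
    dense internal phase track allows exact evaluation at off-grid times
    (e.g. PA window centres vs PPG instants) via :meth:`at`.
    """

    fundamental_hz: float
    harmonic_amps: tuple[float, ...]
    hrv_sd_hz: float
    phase_rad: float
    rate_hz: float
    duration_s: float
    times: np.ndarray
    samples: np.ndarray
    # dense phase track used for off-grid evaluation
    _dense_times: np.ndarray = field(repr=False, default=None)
    _dense_phase: np.ndarray = field(repr=False, default=None)
    _offset: float = 0.0
    _scale: float = 1.0

    def at(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the normalized waveform at arbitrary times within the record."""
        t = np.asarray(t, dtype=float)
        phase = np.interp(t, self._dense_times, self._dense_phase)
        raw = _render(phase, self.harmonic_amps, self.phase_rad)
        return (raw - self._offset) / self._scale


def _render(phase: np.ndarray, harmonic_amps: tuple[float, ...],
            phase0: float) -> np.ndarray:
    out = np.zeros_like(phase)
    for k, a in enumerate(harmonic_amps, start=1):
        out += a * np.sin(k * (phase + phase0))
    return out


def simulate_cardiac_waveform(
    fundamental_hz: float,
    duration_s: float,
    rate_hz: float,
    harmonic_amps: tuple[float, ...] = (1.0,),
    hrv_sd_hz: float = 0.0,
    phase_rad: float = 0.0,
    seed: int | np.random.Generator = 0,
    dense_rate_hz: float = 1000.0,
) -> CardiacWaveform:
    """Generate a unit peak-to-peak cardiac waveform.

    With ``hrv_sd_hz = 0`` the series is strictly periodic and its DFT
    argmax over (0, Nyquist) equals the fundamental (harmonic amplitudes
    are required to be weaker than the fundamental's).
    """
    if fundamental_hz <= 0 or duration_s <= 0 or rate_hz <= 0:
        raise InvalidConfigError("fundamental, duration and rate must be > 0")
    if fundamental_hz >= rate_hz / 2.0:
        raise AliasingError(
            f"fundamental {fundamental_hz} Hz is at or above the Nyquist "
            f"limit {rate_hz / 2.0} Hz"
        )
    if not harmonic_amps or harmonic_amps[0] <= 0:
        raise InvalidConfigError("harmonic_amps must start with a positive fundamental amplitude")
    if any(a > harmonic_amps[0] for a in harmonic_amps[1:]):
        raise InvalidConfigError("harmonics must not exceed the fundamental amplitude")
    if hrv_sd_hz < 0:
        raise InvalidConfigError("hrv_sd_hz must be >= 0")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dt = 1.0 / dense_rate_hz
    n_dense = int(np.ceil(duration_s * dense_rate_hz)) + 1
    t_dense = np.arange(n_dense) * dt

    if hrv_sd_hz > 0:
        # Instantaneous-frequency deviation: Gaussian control points every
        # second, cosine-smoothed, clipped to keep frequency positive.
        n_ctrl = int(np.ceil(duration_s)) + 2
        ctrl = rng.normal(0.0, hrv_sd_hz, n_ctrl)
        tc = np.arange(n_ctrl) * 1.0
        idx = np.clip(np.searchsorted(tc, t_dense, side="right") - 1, 0, n_ctrl - 2)
        frac = (t_dense - tc[idx]) / 1.0
        s = 0.5 - 0.5 * np.cos(np.pi * frac)
        dev = ctrl[idx] * (1 - s) + ctrl[idx + 1] * s
        f_inst = np.clip(fundamental_hz + dev, 0.05 * fundamental_hz, None)
    else:
        f_inst = np.full(n_dense, fundamental_hz)

    phase = 2.0 * np.pi * np.concatenate(
        ([0.0], np.cumsum(0.5 * (f_inst[1:] + f_inst[:-1]) * dt))
    )

    n = int(round(duration_s * rate_hz))
    times = np.arange(n) / rate_hz
    raw_dense = _render(phase, tuple(harmonic_amps), phase_rad)
    lo, hi = raw_dense.min(), raw_dense.max()
    offset = 0.5 * (hi + lo)
    scale = hi - lo if hi > lo else 1.0

    wf = CardiacWaveform(
        fundamental_hz=fundamental_hz,
        harmonic_amps=tuple(harmonic_amps),
        hrv_sd_hz=hrv_sd_hz,
        phase_rad=phase_rad,
        rate_hz=rate_hz,
        duration_s=duration_s,
        times=times,
        samples=np.empty(0),
        _dense_times=t_dense,
        _dense_phase=phase,
        _offset=offset,
        _scale=scale,
    )
    object.__setattr__(wf, "samples", wf.at(times))
    return wf
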