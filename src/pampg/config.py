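"""Configuration dataclasses for acquisition, scene, spectral analysis and pipeline runs.

All µm↔pixel conversions derive from a single source of truth: the axial
pixel pitch is ``speed_of_sound / (2 · digitizer_rate)`` (1.54 µm at the
defaults of 1540 m/s and 500 MS/s), the factor of two accounting for the
acoustic round trip being absent in photoacoustic reception — the wave
travels one way, but axial distance maps to time of flight via the speed of
sound and the digitizer samples that time axis; the lateral pitch is the
scan range divided by the number of A-lines per B-scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError

#: Named random substreams derived from the single top-level seed.
SUBSTREAMS = {"waveform": 0, "frames": 1, "ppg": 2, "mc": 3, "scene": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of a top-level seed.

    Stages (frame rendering, PPG noise, Monte Carlo) draw from disjoint,
    reproducible substreams so each can be re-run independently.
    """
    if name not in SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(SUBSTREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(SUBSTREAMS[name],))
    return np.random.default_rng(ss)


def snr_db_to_ratio(snr_db: float) -> float:
    """Convert an SNR quoted in dB to the plain peak/noise-SD ratio.

    SNR is *defined* here as the ratio of peak vessel amplitude to the noise
    standard deviation, so x dB means a ratio of 10**(x/10): 10 dB → 10.
    """
    return 10.0 ** (snr_db / 10.0)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging-system timing and geometry parameters.

    Defaults mirror a fast-scanning OR-PAM head with an interleaved
    reflectance PPG probe: 50 B-scans/s built from 20 kHz A-lines, a
    500 MS/s digitizer, a ~1 mm lateral scan, and PPG sampled at 50 Hz with
    a 5 V photodiode saturation level.
    """

    frame_rate_hz: float = 50.0
    a_line_rate_hz: float = 20_000.0
    digitizer_rate_hz: float = 5e8
    speed_of_sound_m_s: float = 1540.0
    lateral_range_um: float = 1000.0
    n_axial: int = 512
    n_lateral: int = 200
    ppg_rate_hz: float = 50.0
    ppg_saturation_v: float = 5.0

    def __post_init__(self) -> None:
        for name in ("frame_rate_hz", "a_line_rate_hz", "digitizer_rate_hz",
                     "speed_of_sound_m_s", "lateral_range_um", "ppg_rate_hz",
                     "ppg_saturation_v"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_axial < 1 or self.n_lateral < 1:
            raise InvalidConfigError("grid dimensions must be >= 1")
        # A-lines available during the forward half of one scan cycle.
        max_lines = self.a_line_rate_hz / (2.0 * self.frame_rate_hz)
        if self.n_lateral > max_lines:
            raise InvalidConfigError(
                f"n_lateral={self.n_lateral} exceeds the {max_lines:.0f} A-lines "
                "available in the forward half-cycle"
            )

    @property
    def axial_pitch_um(self) -> float:
        """Axial pixel pitch in µm: speed_of_sound / (2 · digitizer_rate)."""
        return self.speed_of_sound_m_s / (2.0 * self.digitizer_rate_hz) * 1e6

    @property
    def lateral_pitch_um(self) -> float:
        return self.lateral_range_um / self.n_lateral

    @property
    def axial_extent_um(self) -> float:
        return self.n_axial * self.axial_pitch_um


@dataclass(frozen=True)
class Vessel:
    """One vessel cross-section: a Gaussian blob with σ = radius/2."""

    baseline_depth_um: float
    lateral_center_um: float
    radius_um: float = 20.0
    peak_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise InvalidConfigError("vessel radius must be > 0")
        if self.peak_amplitude <= 0:
            raise InvalidConfigError("vessel peak amplitude must be > 0")


@dataclass(frozen=True)
class VesselScene:
    """Geometry and statistics of the rendered B-mode content.

    All vessels share one coherent cardiac motion signal (the paper's
    observation that tracked vessels move with the same pattern); slow
    subject motion is modelled as a sub-1 Hz sinusoid plus a linear term.
    ``noise_sd`` is the additive i.i.d. Gaussian image noise in the same
    arbitrary units as the vessel peak amplitudes.
    """

    surface_depth_um: float = 80.0
    vessels: tuple[Vessel, ...] = ()
    motion_p2p_um: float = 50.0
    drift_freq_hz: float = 0.3
    drift_amp_um: float = 20.0
    drift_slope_um_s: float = 0.1
    noise_sd: float = 0.1
    surface_amplitude: float = 1.5
    surface_sigma_um: float = 8.0

    def __post_init__(self) -> None:
        if self.motion_p2p_um < 0:
            raise InvalidConfigError("motion_p2p_um must be >= 0")
        if not (0 <= self.drift_freq_hz < 1.0):
            raise InvalidConfigError("drift_freq_hz models sub-1 Hz motion; must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        for v in self.vessels:
            if v.baseline_depth_um <= self.surface_depth_um:
                raise InvalidConfigError(
                    f"vessel at {v.baseline_depth_um} µm is not below the "
                    f"skin surface at {self.surface_depth_um} µm"
                )


def default_scene(n_vessels: int = 5, snr_db: float = 10.0,
                  motion_p2p_um: float = 50.0) -> VesselScene:
    """Five-vessel finger scene at the stated image SNR.

    Vessels are spread in depth (250–550 µm) and across the lateral field,
    as in a cross-sectional finger B-scan.
    """
    depths = np.linspace(250.0, 550.0, n_vessels)
    laterals = np.linspace(150.0, 850.0, n_vessels)
    vessels = tuple(
        Vessel(baseline_depth_um=float(d), lateral_center_um=float(x))
        for d, x in zip(depths, laterals)
    )
    return VesselScene(
        vessels=vessels,
        motion_p2p_um=motion_p2p_um,
        noise_sd=1.0 / snr_db_to_ratio(snr_db),
    )


@dataclass(frozen=True)
class BandConfig:
    """Spectral-analysis settings for heart-rate extraction.

    ``highpass_cutoff_hz`` suppresses sub-1 Hz subject motion;
    ``search_band_hz`` brackets plausible human heart rates (0.8–3 Hz,
    48–180 BPM); ``pulsatility_threshold`` is the median-normalised peak
    power above which a channel is called pulsatile, calibrated so 60 s of
    white noise yields < 1% false positives.
    """

    highpass_cutoff_hz: float = 1.0
    search_band_hz: tuple[float, float] = (0.8, 3.0)
    pad_factor: int = 8
    window: str = "hann"
    pulsatility_threshold: float = 20.0

    def __post_init__(self) -> None:
        lo, hi = self.search_band_hz
        if not (0 < lo < hi):
            raise InvalidConfigError("search band must satisfy 0 < low < high")
        if self.highpass_cutoff_hz <= 0:
            raise InvalidConfigError("highpass cutoff must be > 0")
        if self.pad_factor < 1:
            raise InvalidConfigError("pad_factor must be >= 1")


@dataclass(frozen=True)
class PPGConfig:
    """Photodiode channel model: baseline − gain·waveform + noise, clipped."""

    gain_v: float = 1.0
    baseline_v: float = 2.5
    noise_sd_v: float = 0.01

    def __post_init__(self) -> None:
        if self.baseline_v < 0:
            raise InvalidConfigError("PPG baseline must be >= 0")
        if self.noise_sd_v < 0:
            raise InvalidConfigError("PPG noise SD must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one trial end to end."""

    scenario: str = "normal"
    heart_rate_hz: float = 1.35
    duration_s: float = 60.0
    seed: int = 0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    scene: VesselScene = field(default_factory=default_scene)
    band: BandConfig = field(default_factory=BandConfig)
    ppg: PPGConfig = field(default_factory=PPGConfig)
    harmonic_amps: tuple[float, ...] = (1.0, 0.3, 0.1)
    hrv_sd_hz: float = 0.0
    waveform_phase_rad: float = 0.0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("normal", "occluded"):
            raise InvalidConfigError(
                f"unknown scenario {self.scenario!r}; expected 'normal' or 'occluded'"
            )
        if self.heart_rate_hz <= 0:
            raise InvalidConfigError("heart_rate_hz must be > 0")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be > 0")


# ---------------------------------------------------------------------------
# dict / YAML round-tripping

def config_to_dict(cfg) -> dict:
    """Recursively convert a config dataclass to plain JSON/YAML-able types."""
    def conv(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {f.name: conv(getattr(x, f.name)) for f in dataclasses.fields(x)}
        if isinstance(x, (tuple, list)):
            return [conv(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        return x
    return conv(cfg)


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "acquisition" in d:
        d["acquisition"] = AcquisitionConfig(**d["acquisition"])
    if "scene" in d:
        sc = dict(d["scene"])
        sc["vessels"] = tuple(Vessel(**v) for v in sc.get("vessels", ()))
        d["scene"] = VesselScene(**sc)
    if "band" in d:
        b = dict(d["band"])
        if "search_band_hz" in b:
            b["search_band_hz"] = tuple(b["search_band_hz"])
        d["band"] = BandConfig(**b)
    if "ppg" in d:
        d["ppg"] = PPGConfig(**d["ppg"])
    if "harmonic_amps" in d:
        d["harmonic_amps"] = tuple(d["harmonic_amps"])
    return PipelineConfig(**d)
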