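"""Synthetic paired PAM frame stacks and PPG traces.

Each trial emulates one interleaved acquisition: a B-mode stack whose
vessel cross-sections oscillate axially with a shared cardiac waveform
(plus sub-1 Hz drift), and a photodiode trace modulated by the same
waveform, both sampled on the schedule of a single hardware counter.
Under the occluded scenario the cardiac motion amplitude and the PPG
cardiac gain are both zero while drift and noise persist.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import (
    AcquisitionConfig,
    PipelineConfig,
    PPGConfig,
    VesselScene,
    substream,
)
from .errors import InvalidConfigError, OutOfFieldError
from .timing import TimingSchedule, make_timing_schedule
from .tracking import FrameStack
from .waveform import CardiacWaveform, simulate_cardiac_waveform

SCENARIOS = ("normal", "occluded")


@dataclass(frozen=True)
class PPGTrace:
    """Timestamped photodiode voltages."""

    timestamps: np.ndarray
    voltage_v: np.ndarray
    saturation_v: float
    scenario: str = "normal"

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame truth recorded by the generator."""

    vessel_positions_um: np.ndarray   # (n_frames, n_vessels) absolute depth
    motion_um: np.ndarray             # shared cardiac motion at frame times
    drift_um: np.ndarray              # drift component at frame times
    cardiac_fundamental_hz: float
    motion_p2p_um: float


@dataclass(frozen=True)
class Trial:
    """One complete synthetic acquisition."""

    frame_stack: FrameStack
    ppg: PPGTrace
    schedule: TimingSchedule
    ground_truth: GroundTruth
    scenario: str
    waveform: CardiacWaveform
    config: PipelineConfig | None = None


def _drift(scene: VesselScene, t: np.ndarray, phase: float = 0.0) -> np.ndarray:
    d = scene.drift_amp_um * np.sin(2.0 * np.pi * scene.drift_freq_hz * t + phase)
    return d + scene.drift_slope_um_s * (t - t.mean())


def simulate_frame_stack(
    scene: VesselScene,
    waveform: CardiacWaveform,
    config: AcquisitionConfig,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    schedule: TimingSchedule | None = None,
    motion_p2p_um: float | None = None,
    drift_phase_rad: float = 0.0,
) -> tuple[FrameStack, GroundTruth]:
    """Render the B-mode stack and record the ground truth.

    Each frame is a bright skin-surface band plus one 2-D Gaussian blob per
    vessel (σ = radius/2 in both axes), displaced axially by the shared
    cardiac motion plus drift, with additive i.i.d. Gaussian noise.
    Raises :class:`OutOfFieldError` if any vessel can leave the grid at its
    displacement extremes.
    """
    if not scene.vessels:
        raise InvalidConfigError("scene contains no vessels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if schedule is None:
        schedule = make_timing_schedule(config, duration_s)
    t = schedule.pa_frame_timestamps
    nt = len(t)
    p2p = scene.motion_p2p_um if motion_p2p_um is None else motion_p2p_um

    motion = p2p * waveform.at(t)          # waveform is unit p2p
    drift = _drift(scene, t, drift_phase_rad)
    dz = motion + drift                     # µm, common to all vessels

    pitch_a = config.axial_pitch_um
    pitch_l = config.lateral_pitch_um
    na, nl = config.n_axial, config.n_lateral

    # field-of-view check at the realized extremes, with a 3σ blob margin
    for v in scene.vessels:
        margin = 1.5 * v.radius_um  # 3σ with σ = radius/2
        zmin = v.baseline_depth_um + dz.min() - margin
        zmax = v.baseline_depth_um + dz.max() + margin
        if zmin < 0 or zmax > na * pitch_a:
            raise OutOfFieldError(
                f"vessel at {v.baseline_depth_um} µm leaves the axial field "
                f"([{zmin:.0f}, {zmax:.0f}] µm vs [0, {na * pitch_a:.0f}] µm)"
            )
        if not (0 <= v.lateral_center_um <= nl * pitch_l):
            raise OutOfFieldError(
                f"vessel lateral centre {v.lateral_center_um} µm outside scan range"
            )

    az_um = (np.arange(na) + 0.5) * pitch_a
    lat_um = (np.arange(nl) + 0.5) * pitch_l

    base = np.zeros((na, nl), dtype=np.float32)
    if scene.surface_amplitude > 0:
        surf = scene.surface_amplitude * np.exp(
            -0.5 * ((az_um - scene.surface_depth_um) / scene.surface_sigma_um) ** 2
        )
        base += surf[:, None].astype(np.float32)

    # per-vessel fixed lateral profile and sliced axial windows for speed
    lat_profs = []
    for v in scene.vessels:
        sig = v.radius_um / 2.0
        lp = np.exp(-0.5 * ((lat_um - v.lateral_center_um) / sig) ** 2)
        cols = np.nonzero(lp > 1e-6)[0]
        lat_profs.append((cols, lp[cols].astype(np.float32)))

    data = np.empty((nt, na, nl), dtype=np.float32)
    truth = np.empty((nt, len(scene.vessels)))
    for k in range(nt):
        frame = base.copy()
        if scene.noise_sd > 0:
            frame += rng.normal(0.0, scene.noise_sd, (na, nl)).astype(np.float32)
        for j, v in enumerate(scene.vessels):
            z = v.baseline_depth_um + dz[k]
            truth[k, j] = z
            sig = v.radius_um / 2.0
            a0 = max(0, int((z - 4 * sig) / pitch_a))
            a1 = min(na, int(np.ceil((z + 4 * sig) / pitch_a)) + 1)
            ax = (v.peak_amplitude
                  * np.exp(-0.5 * ((az_um[a0:a1] - z) / sig) ** 2)).astype(np.float32)
            cols, lp = lat_profs[j]
            frame[a0:a1, cols[0]:cols[-1] + 1] += np.outer(ax, lp)
        data[k] = frame

    stack = FrameStack(
        data=data,
        axial_pitch_um=pitch_a,
        lateral_pitch_um=pitch_l,
        timestamps=t.copy(),
    )
    gt = GroundTruth(
        vessel_positions_um=truth,
        motion_um=motion,
        drift_um=drift,
        cardiac_fundamental_hz=waveform.fundamental_hz,
        motion_p2p_um=float(p2p),
    )
    return stack, gt


def simulate_ppg(
    waveform: CardiacWaveform,
    config: AcquisitionConfig,
    ppg: PPGConfig = PPGConfig(),
    occluded: bool = False,
    seed: int | np.random.Generator = 0,
    schedule: TimingSchedule | None = None,
    duration_s: float | None = None,
) -> PPGTrace:
    """Photodiode trace: clip(baseline − gain·waveform + noise, 0, saturation).

    Reflectance polarity: systolic blood-volume increase absorbs more light,
    so the detected voltage *drops* with the waveform.  Occlusion forces the
    cardiac gain to zero; baseline and noise persist.
    """
    if schedule is None:
        if duration_s is None:
            raise InvalidConfigError("either schedule or duration_s is required")
        schedule = make_timing_schedule(config, duration_s)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = schedule.ppg_sample_timestamps
    gain = 0.0 if occluded else ppg.gain_v
    v = ppg.baseline_v - gain * waveform.at(t)
    if ppg.noise_sd_v > 0:
        v = v + rng.normal(0.0, ppg.noise_sd_v, len(t))
    v = np.clip(v, 0.0, config.ppg_saturation_v)
    return PPGTrace(
        timestamps=t.copy(),
        voltage_v=v,
        saturation_v=config.ppg_saturation_v,
        scenario="occluded" if occluded else "normal",
    )


def simulate_trial(config: PipelineConfig, seed: int | None = None) -> Trial:
    """Generate one paired trial; both channels share one waveform and schedule.

    Identical (config, seed) pairs produce bit-identical trials: every
    random stage draws from a named substream of the single top-level seed.
    """
    if config.scenario not in SCENARIOS:
        raise InvalidConfigError(f"unknown scenario {config.scenario!r}")
    top_seed = config.seed if seed is None else seed
    occluded = config.scenario == "occluded"

    schedule = make_timing_schedule(config.acquisition, config.duration_s)
    wf = simulate_cardiac_waveform(
        config.heart_rate_hz,
        config.duration_s,
        config.acquisition.frame_rate_hz,
        harmonic_amps=config.harmonic_amps,
        hrv_sd_hz=config.hrv_sd_hz,
        phase_rad=config.waveform_phase_rad,
        seed=substream(top_seed, "waveform"),
    )
    p2p = 0.0 if occluded else config.scene.motion_p2p_um
    stack, gt = simulate_frame_stack(
        config.scene, wf, config.acquisition, config.duration_s,
        seed=substream(top_seed, "frames"), schedule=schedule,
        motion_p2p_um=p2p,
    )
    ppg = simulate_ppg(
        wf, config.acquisition, config.ppg, occluded=occluded,
        seed=substream(top_seed, "ppg"), schedule=schedule,
    )
    return Trial(
        frame_stack=stack, ppg=ppg, schedule=schedule, ground_truth=gt,
        scenario=config.scenario, waveform=wf,
        config=replace(config, seed=top_seed),
    )
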