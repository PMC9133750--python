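"""Readers and writers for all pipeline artifacts.

Frame stacks travel as multi-page TIFF (time-major) with a JSON sidecar
carrying the pixel pitches, frame timestamps and, optionally, the
generator's ground truth — the sidecar is mandatory on read so that pixel
units are never silently assumed.  Traces, tracks and spectra are CSV with
snake_case, unit-suffixed columns; configs round-trip through YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import PipelineConfig, config_to_dict, pipeline_config_from_dict
from .errors import MetadataError
from .synthesis import PPGTrace
from .timing import TimingSchedule
from .tracking import FrameStack, MotionTrace, VesselTrack

_SIDECAR_KEYS = ("axial_pitch_um", "lateral_pitch_um", "timestamps_s")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame_stack(stack: FrameStack, path: str | Path,
                      extra_meta: dict | None = None) -> Path:
    """Write a stack as multi-page TIFF plus its JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    meta = {
        "axial_pitch_um": stack.axial_pitch_um,
        "lateral_pitch_um": stack.lateral_pitch_um,
        "timestamps_s": np.asarray(stack.timestamps, dtype=float).tolist(),
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_frame_stack(path: str | Path) -> tuple[FrameStack, dict]:
    """Read a TIFF stack and its sidecar; returns (stack, full metadata dict).

    Raises :class:`MetadataError` naming the missing sidecar or key rather
    than assuming default pixel pitches.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"metadata sidecar {sidecar} is required")
    meta = json.loads(sidecar.read_text())
    for key in _SIDECAR_KEYS:
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar} is missing required key {key!r}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    stack = FrameStack(
        data=data,
        axial_pitch_um=float(meta["axial_pitch_um"]),
        lateral_pitch_um=float(meta["lateral_pitch_um"]),
        timestamps=np.asarray(meta["timestamps_s"], dtype=float),
    )
    return stack, meta


def write_ppg_trace(trace: PPGTrace, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# saturation_v={trace.saturation_v}\n")
        fh.write(f"# scenario={trace.scenario}\n")
        pd.DataFrame({"time_s": trace.timestamps,
                      "voltage_V": trace.voltage_v}).to_csv(fh, index=False)
    return path


def read_ppg_trace(path: str | Path) -> PPGTrace:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    return PPGTrace(
        timestamps=df["time_s"].to_numpy(),
        voltage_v=df["voltage_V"].to_numpy(),
        saturation_v=float(meta.get("saturation_v", 5.0)),
        scenario=meta.get("scenario", "normal"),
    )


def write_tracks(tracks: list[VesselTrack], path: str | Path) -> Path:
    frames = [
        pd.DataFrame({
            "time_s": tr.timestamps,
            "vessel_id": tr.vessel_id,
            "position_um": tr.positions_um,
        })
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def write_motion_trace(trace: MotionTrace, path: str | Path) -> Path:
    pd.DataFrame({"time_s": trace.timestamps,
                  "position_um": trace.positions_um}).to_csv(path, index=False)
    return Path(path)


def read_motion_trace(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path, comment="#")
    return MotionTrace(timestamps=df["time_s"].to_numpy(),
                       positions_um=df["position_um"].to_numpy())


def write_spectrum(spectrum, path: str | Path) -> Path:
    pd.DataFrame({"freq_hz": spectrum.freqs_hz,
                  "power": spectrum.power}).to_csv(path, index=False)
    return Path(path)


def write_schedule(schedule: TimingSchedule, path: str | Path) -> Path:
    Path(path).write_text(json.dumps({
        "cycle_period_s": schedule.cycle_period_s,
        "pa_window_start_offset_s": schedule.pa_window_start_offset_s,
        "pa_window_duration_s": schedule.pa_window_duration_s,
        "pa_frame_timestamps_s": schedule.pa_frame_timestamps.tolist(),
        "ppg_sample_timestamps_s": schedule.ppg_sample_timestamps.tolist(),
    }, indent=1))
    return Path(path)


def read_schedule(path: str | Path) -> TimingSchedule:
    d = json.loads(Path(path).read_text())
    return TimingSchedule(
        cycle_period_s=d["cycle_period_s"],
        pa_window_start_offset_s=d["pa_window_start_offset_s"],
        pa_window_duration_s=d["pa_window_duration_s"],
        pa_frame_timestamps=np.asarray(d["pa_frame_timestamps_s"]),
        ppg_sample_timestamps=np.asarray(d["ppg_sample_timestamps_s"]),
    )


def write_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))
    return path


def read_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return pipeline_config_from_dict(d)
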