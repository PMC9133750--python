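"""Shared fixtures: small, fast acquisition geometries for unit tests."""

import numpy as np
import pytest

from pampg import (
    AcquisitionConfig,
    BandConfig,
    PipelineConfig,
    PPGConfig,
    Vessel,
    VesselScene,
)


@pytest.fixture
def small_acq() -> AcquisitionConfig:
    """Quarter-size grid (256 axial × 64 lateral) for fast rendering."""
    return AcquisitionConfig(n_axial=256, n_lateral=64, lateral_range_um=320.0)


@pytest.fixture
def small_scene() -> VesselScene:
    return small_scene_factory()


def small_scene_factory(n_vessels: int = 3, noise_sd: float = 0.1,
                        motion_p2p_um: float = 50.0,
                        drift_amp_um: float = 15.0) -> VesselScene:
    depths = [180.0, 250.0, 320.0][:n_vessels]
    laterals = [80.0, 160.0, 240.0][:n_vessels]
    vessels = tuple(Vessel(d, x) for d, x in zip(depths, laterals))
    return VesselScene(
        surface_depth_um=60.0,
        vessels=vessels,
        motion_p2p_um=motion_p2p_um,
        drift_freq_hz=0.3,
        drift_amp_um=drift_amp_um,
        noise_sd=noise_sd,
    )


def small_config(scenario: str = "normal", hr_hz: float = 1.35,
                 duration_s: float = 12.0, seed: int = 0,
                 hrv_sd_hz: float = 0.0, **scene_kw) -> PipelineConfig:
    """A fast-but-realistic trial config on the quarter-size grid."""
    return PipelineConfig(
        scenario=scenario,
        heart_rate_hz=hr_hz,
        duration_s=duration_s,
        seed=seed,
        acquisition=AcquisitionConfig(n_axial=256, n_lateral=64,
                                      lateral_range_um=320.0),
        scene=small_scene_factory(**scene_kw),
        band=BandConfig(),
        ppg=PPGConfig(),
        hrv_sd_hz=hrv_sd_hz,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
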