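"""Frame-stack and PPG generators: rendering, clipping, scenario contracts."""

import dataclasses

import numpy as np
import pytest

from pampg import (
    AcquisitionConfig,
    PPGConfig,
    Vessel,
    VesselROI,
    VesselScene,
    find_max_pixel,
    make_timing_schedule,
    simulate_cardiac_waveform,
    simulate_frame_stack,
    simulate_ppg,
    simulate_trial,
    track_vessel,
)
from pampg.errors import InvalidConfigError, OutOfFieldError

from conftest import small_config, small_scene_factory


def _acq():
    return AcquisitionConfig(n_axial=256, n_lateral=64, lateral_range_um=320.0)


def test_static_noise_free_scene_gives_identical_frames():
    scene = small_scene_factory(noise_sd=0.0, motion_p2p_um=0.0, drift_amp_um=0.0)
    scene = dataclasses.replace(scene, drift_slope_um_s=0.0)
    wf = simulate_cardiac_waveform(1.35, 2.0, 50.0)
    stack, _ = simulate_frame_stack(scene, wf, _acq(), 2.0, seed=0)
    for k in (1, 25, 50, 99):
        assert np.array_equal(stack.data[0], stack.data[k])


def test_noise_free_argmax_hits_rendered_blob_center():
    scene = small_scene_factory(n_vessels=1, noise_sd=0.0, motion_p2p_um=0.0,
                                drift_amp_um=0.0)
    scene = dataclasses.replace(scene, drift_slope_um_s=0.0)
    acq = _acq()
    wf = simulate_cardiac_waveform(1.35, 1.0, 50.0)
    stack, gt = simulate_frame_stack(scene, wf, acq, 1.0, seed=0)
    v = scene.vessels[0]
    roi = VesselROI.centered(int(v.baseline_depth_um / acq.axial_pitch_um),
                             int(v.lateral_center_um / acq.lateral_pitch_um),
                             bounds=stack.shape)
    ia, il = find_max_pixel(stack.data[0], roi)
    # pixel centres sit at (i + 0.5) · pitch
    assert abs((ia + 0.5) * acq.axial_pitch_um - gt.vessel_positions_um[0, 0]) \
        <= acq.axial_pitch_um
    assert abs((il + 0.5) * acq.lateral_pitch_um - v.lateral_center_um) \
        <= acq.lateral_pitch_um


def test_tracked_trajectory_matches_ground_truth_log():
    """SNR 20 dB, 50 µm p2p: tracked trace correlates > 0.99 with the truth."""
    cfg = small_config(seed=1, duration_s=12.0, noise_sd=0.01)  # 20 dB
    trial = simulate_trial(cfg)
    acq = cfg.acquisition
    v = cfg.scene.vessels[0]
    roi = VesselROI.centered(int(v.baseline_depth_um / acq.axial_pitch_um),
                             int(v.lateral_center_um / acq.lateral_pitch_um),
                             bounds=trial.frame_stack.shape)
    track = track_vessel(trial.frame_stack, roi)
    truth = trial.ground_truth.vessel_positions_um[:, 0]
    r = np.corrcoef(track.positions_um, truth)[0, 1]
    assert r > 0.99


def test_vessel_leaving_grid_raises_out_of_field():
    scene = small_scene_factory(n_vessels=1, motion_p2p_um=600.0)
    wf = simulate_cardiac_waveform(1.35, 1.0, 50.0)
    with pytest.raises(OutOfFieldError):
        simulate_frame_stack(scene, wf, _acq(), 1.0, seed=0)


def test_ppg_saturates_at_exactly_5v():
    """baseline 4.9 V with 1 V swing clips at the 5 V photodiode limit."""
    acq = AcquisitionConfig()
    wf = simulate_cardiac_waveform(1.4, 20.0, 50.0)
    ppg = simulate_ppg(wf, acq, PPGConfig(gain_v=1.0, baseline_v=4.9, noise_sd_v=0.0),
                       duration_s=20.0)
    unclipped = 4.9 - 1.0 * wf.at(ppg.timestamps)
    over = unclipped > 5.0
    assert over.any()
    assert np.all(ppg.voltage_v[over] == 5.0)
    assert np.allclose(ppg.voltage_v[~over], unclipped[~over])
    assert ppg.voltage_v.max() == 5.0


def test_ppg_dominant_frequency_matches_drive():
    acq = AcquisitionConfig()
    wf = simulate_cardiac_waveform(1.4, 60.0, 50.0)
    ppg = simulate_ppg(wf, acq, PPGConfig(noise_sd_v=0.01), duration_s=60.0, seed=3)
    x = ppg.voltage_v - ppg.voltage_v.mean()
    p = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / 50.0)
    assert f[np.argmax(p[1:]) + 1] == pytest.approx(1.4, abs=1 / 60.0)


def test_occluded_ppg_has_no_cardiac_band_excess():
    """With gain forced to 0 the cardiac band holds only its share of white noise."""
    acq = AcquisitionConfig()
    wf = simulate_cardiac_waveform(1.4, 60.0, 50.0)
    ppg = simulate_ppg(wf, acq, PPGConfig(noise_sd_v=0.02), occluded=True,
                       duration_s=60.0, seed=4)
    x = ppg.voltage_v - ppg.voltage_v.mean()
    p = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / 50.0)
    band = (f >= 0.8) & (f <= 3.0)
    # in-band mean power ≈ broadband mean power (white), well within 3× either way
    ratio = p[band].mean() / p[1:].mean()
    assert 1 / 3 < ratio < 3


def test_trial_is_bit_identical_under_same_seed():
    a = simulate_trial(small_config(seed=42, duration_s=2.0))
    b = simulate_trial(small_config(seed=42, duration_s=2.0))
    assert np.array_equal(a.frame_stack.data, b.frame_stack.data)
    assert np.array_equal(a.ppg.voltage_v, b.ppg.voltage_v)
    assert np.array_equal(a.ground_truth.vessel_positions_um,
                          b.ground_truth.vessel_positions_um)


def test_occluded_trial_contract():
    trial = simulate_trial(small_config(scenario="occluded", seed=42, duration_s=2.0))
    assert trial.ground_truth.motion_p2p_um == 0.0
    assert np.all(trial.ground_truth.motion_um == 0.0)
    # PPG carries no cardiac modulation: only noise around the baseline
    assert trial.ppg.voltage_v.std() < 5 * trial.config.ppg.noise_sd_v


def test_unknown_scenario_rejected():
    with pytest.raises(InvalidConfigError):
        small_config(scenario="hyperemia")


def test_trial_channels_share_schedule():
    trial = simulate_trial(small_config(seed=1, duration_s=2.0))
    assert np.array_equal(trial.frame_stack.timestamps,
                          trial.schedule.pa_frame_timestamps)
    assert np.array_equal(trial.ppg.timestamps,
                          trial.schedule.ppg_sample_timestamps)
    # PA frames sit half a cycle after the PPG samples
    assert np.allclose(trial.frame_stack.timestamps - trial.ppg.timestamps, 0.01)


def test_scene_validation():
    with pytest.raises(InvalidConfigError):
        VesselScene(surface_depth_um=100.0, vessels=(Vessel(50.0, 100.0),))
    with pytest.raises(InvalidConfigError):
        small_scene_factory(motion_p2p_um=-1.0)
    with pytest.raises(InvalidConfigError):
        VesselScene(drift_freq_hz=1.5)
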