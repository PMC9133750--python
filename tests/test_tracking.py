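"""Max-pixel localization and multi-vessel averaging."""

import dataclasses

import numpy as np
import pytest

from pampg import (
    FrameStack,
    VesselROI,
    VesselTrack,
    average_tracks,
    find_max_pixel,
    peak_to_peak_amplitude,
    simulate_cardiac_waveform,
    simulate_frame_stack,
    simulate_trial,
    track_vessel,
)
from pampg.errors import (
    AlignmentError,
    DegenerateROIWarning,
    ROIError,
    TrackingLostError,
)
from pampg.spectral import detrend_highpass

from conftest import small_config, small_scene_factory


def _brute_force_argmax(frame, roi):
    """Exhaustive double-loop scan: the independent localization oracle."""
    best = None
    best_val = -np.inf
    for a in range(roi.axial_start, roi.axial_stop):
        for l in range(roi.lateral_start, roi.lateral_stop):
            if frame[a, l] > best_val:
                best_val = frame[a, l]
                best = (a, l)
    return best


def test_unique_maximum_found():
    frame = np.zeros((64, 64))
    frame[12, 30] = 7.0
    roi = VesselROI(0, 64, 0, 64)
    assert find_max_pixel(frame, roi) == (12, 30)


def test_ties_break_to_smallest_axial_then_lateral():
    frame = np.zeros((32, 32))
    frame[10, 5] = frame[20, 5] = 3.0
    assert find_max_pixel(frame, VesselROI(0, 32, 0, 32)) == (10, 5)
    frame2 = np.zeros((32, 32))
    frame2[10, 5] = frame2[10, 2] = 3.0
    assert find_max_pixel(frame2, VesselROI(0, 32, 0, 32)) == (10, 2)


def test_matches_brute_force_oracle_on_random_frames(rng):
    """1,000 random frames and ROIs: argmax identical to the exhaustive scan."""
    for _ in range(1000):
        frame = rng.normal(size=(48, 40))
        a0 = int(rng.integers(0, 30))
        l0 = int(rng.integers(0, 25))
        roi = VesselROI(a0, a0 + int(rng.integers(2, 48 - a0 + 1)),
                        l0, l0 + int(rng.integers(2, 40 - l0 + 1)))
        assert find_max_pixel(frame, roi) == _brute_force_argmax(frame, roi)


def test_flat_roi_warns_and_returns_origin():
    frame = np.ones((16, 16))
    with pytest.warns(DegenerateROIWarning):
        assert find_max_pixel(frame, VesselROI(4, 8, 6, 10)) == (4, 6)


def test_out_of_bounds_roi_rejected():
    frame = np.zeros((16, 16))
    with pytest.raises(ROIError):
        find_max_pixel(frame, VesselROI(0, 20, 0, 8))
    with pytest.raises(ROIError):
        VesselROI(5, 5, 0, 8)  # empty


def _static_stack(n_frames=10, pos=(20, 12)):
    data = np.zeros((n_frames, 48, 32), dtype=np.float32)
    data[:, pos[0], pos[1]] = 5.0
    return FrameStack(data=data, axial_pitch_um=1.54, lateral_pitch_um=5.0,
                      timestamps=np.arange(n_frames) * 0.02)


def test_static_blob_gives_constant_position():
    track = track_vessel(_static_stack(), VesselROI(8, 40, 4, 28))
    assert np.all(track.pixel_positions == 20)
    assert track.positions_um.var() == 0.0


def test_translation_equivariance():
    """Shifting frame content by k axial pixels shifts the track by exactly k."""
    stack = _static_stack(n_frames=6)
    shifted = FrameStack(data=np.roll(stack.data, 7, axis=1),
                         axial_pitch_um=stack.axial_pitch_um,
                         lateral_pitch_um=stack.lateral_pitch_um,
                         timestamps=stack.timestamps)
    roi = VesselROI(8, 40, 4, 28)
    t0 = track_vessel(stack, roi)
    t1 = track_vessel(shifted, roi)
    assert np.all(t1.pixel_positions - t0.pixel_positions == 7)


def test_noise_free_tracking_within_one_axial_pixel():
    cfg = small_config(seed=0, duration_s=6.0, noise_sd=0.0)
    trial = simulate_trial(cfg)
    acq = cfg.acquisition
    v = cfg.scene.vessels[0]
    roi = VesselROI.centered(int(v.baseline_depth_um / acq.axial_pitch_um),
                             int(v.lateral_center_um / acq.lateral_pitch_um),
                             bounds=trial.frame_stack.shape)
    track = track_vessel(trial.frame_stack, roi)
    truth = trial.ground_truth.vessel_positions_um[:, 0]
    # compare oscillations: integer-pixel quantization allows 1 pixel
    err = (track.positions_um - track.positions_um.mean()) - (truth - truth.mean())
    assert np.max(np.abs(err)) <= acq.axial_pitch_um


def test_p2p_recovery_within_ten_percent_at_stated_snr():
    """Normal trial, 50 µm p2p, SNR 10 dB: recovered p2p within 10%."""
    cfg = small_config(seed=3, duration_s=20.0)  # noise_sd 0.1 = 10 dB
    trial = simulate_trial(cfg)
    acq = cfg.acquisition
    v = cfg.scene.vessels[0]
    roi = VesselROI.centered(int(v.baseline_depth_um / acq.axial_pitch_um),
                             int(v.lateral_center_um / acq.lateral_pitch_um),
                             bounds=trial.frame_stack.shape)
    track = track_vessel(trial.frame_stack, roi)
    hp = detrend_highpass(track.positions_um, 50.0, 1.0)
    assert peak_to_peak_amplitude(hp) == pytest.approx(50.0, rel=0.10)


def test_tracking_lost_when_roi_cannot_cover_field():
    stack = _static_stack()
    with pytest.raises((TrackingLostError, ROIError)):
        track_vessel(stack, VesselROI(100, 120, 0, 8))


def test_subpixel_refinement_tightens_quantization():
    scene = small_scene_factory(n_vessels=1, noise_sd=0.0, drift_amp_um=0.0)
    scene = dataclasses.replace(scene, drift_slope_um_s=0.0)
    from pampg import AcquisitionConfig
    acq = AcquisitionConfig(n_axial=256, n_lateral=64, lateral_range_um=320.0)
    wf = simulate_cardiac_waveform(1.35, 6.0, 50.0)
    stack, gt = simulate_frame_stack(scene, wf, acq, 6.0, seed=0)
    v = scene.vessels[0]
    roi = VesselROI.centered(int(v.baseline_depth_um / acq.axial_pitch_um),
                             int(v.lateral_center_um / acq.lateral_pitch_um),
                             bounds=stack.shape)
    coarse = track_vessel(stack, roi, subpixel=False)
    fine = track_vessel(stack, roi, subpixel=True)
    truth = gt.vessel_positions_um[:, 0]

    def rms(track):
        osc = track.positions_um - track.positions_um.mean()
        return np.sqrt(np.mean((osc - (truth - truth.mean())) ** 2))

    assert rms(fine) < rms(coarse)


def _make_track(vid, positions, dt=0.02):
    positions = np.asarray(positions, dtype=float)
    return VesselTrack(vessel_id=vid, pixel_positions=positions / 1.54,
                       positions_um=positions,
                       timestamps=np.arange(len(positions)) * dt)


def test_average_of_identical_tracks_is_their_demeaned_shape():
    pos = 300 + 25 * np.sin(np.linspace(0, 12 * np.pi, 500))
    avg = average_tracks([_make_track(0, pos), _make_track(1, pos)])
    assert np.allclose(avg.positions_um, pos - pos.mean())


def test_baseline_offsets_cancel_in_average():
    osc = 25 * np.sin(np.linspace(0, 12 * np.pi, 500))
    avg = average_tracks([_make_track(0, 200 + osc), _make_track(1, 450 + osc)])
    assert np.allclose(avg.positions_um, osc - osc.mean())


def test_averaging_reduces_noise_like_sqrt_n(rng):
    """Residual SD of a 5-track average ≈ σ/√5 (Monte Carlo, 200 seeds)."""
    sigma = 3.0
    n, n_tracks = 400, 5
    ratios = []
    for _ in range(200):
        osc = 25 * np.sin(np.linspace(0, 10 * np.pi, n))
        tracks = [_make_track(i, 300 + osc + rng.normal(0, sigma, n))
                  for i in range(n_tracks)]
        avg = average_tracks(tracks)
        resid = avg.positions_um - (osc - osc.mean())
        ratios.append(resid.std() / (sigma / np.sqrt(n_tracks)))
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)


def test_mismatched_tracks_rejected():
    a = _make_track(0, np.zeros(10))
    b = _make_track(1, np.zeros(12))
    with pytest.raises(AlignmentError):
        average_tracks([a, b])
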