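"""Generate a synthetic trial and track its vessels frame by frame.

A 20 s acquisition at 50 B-scans/s renders five vessel cross-sections that
all oscillate axially with a 1.35 Hz cardiac waveform (50 µm peak-to-peak)
on top of slow subject drift.  Each vessel is tracked by locating the
maximum-intensity pixel inside its ROI on every frame; the de-meaned tracks
are averaged into the vascular-motion trace.
"""

import numpy as np

from pampg import PipelineConfig, average_tracks, simulate_trial
from pampg.pipeline import track_all_vessels

config = PipelineConfig(heart_rate_hz=1.35, duration_s=20.0, seed=11)
trial = simulate_trial(config)
print(f"simulated {trial.frame_stack.n_frames} frames "
      f"({trial.frame_stack.shape[0]}×{trial.frame_stack.shape[1]} px, "
      f"axial pitch {trial.frame_stack.axial_pitch_um:.2f} µm)")

tracks = track_all_vessels(trial)
for tr in tracks:
    truth = trial.ground_truth.vessel_positions_um[:, tr.vessel_id]
    rms = np.sqrt(np.mean(((tr.positions_um - tr.positions_um.mean())
                           - (truth - truth.mean())) ** 2))
    print(f"vessel {tr.vessel_id}: depth ≈ {tr.positions_um.mean():.0f} µm, "
          f"tracking RMS error {rms:.2f} µm")

motion = average_tracks(tracks)
corr = np.corrcoef(motion.positions_um,
                   trial.ground_truth.motion_um + trial.ground_truth.drift_um)[0, 1]
print(f"averaged motion trace: correlation with generator truth r = {corr:.4f}")
print("RMS errors of ~2 µm show integer-pixel localization works well below")
print("the 50 µm cardiac excursion; averaging five coherent vessels tightens it.")
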