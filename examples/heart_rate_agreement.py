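"""Extract the heart rate independently from both channels and compare.

The full pipeline on a 60 s normal trial: track vessels → average → high-pass
at 1 Hz → zero-padded periodogram → in-band dominant frequency, done
identically for the vascular-motion trace (imaging channel) and the PPG
voltage (photodiode channel).  The two dominant frequencies should coincide
within one spectral grid bin, and the band-passed channels should be in
phase.
"""

from pampg import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(heart_rate_hz=1.35, duration_s=60.0, seed=42))

print(f"vascular motion : {report.pam_dominant_freq_hz:.3f} Hz "
      f"= {report.pam_bpm:.1f} BPM")
print(f"PPG             : {report.ppg_dominant_freq_hz:.3f} Hz "
      f"= {report.ppg_bpm:.1f} BPM")
print(f"agreement       : {report.agreement.agree} "
      f"(|Δf| = {abs(report.agreement.freq_difference_hz):.4f} Hz, "
      f"tolerance {report.agreement.tolerance_hz:.4f} Hz)")
print(f"displacement    : {report.motion_p2p_um:.1f} µm peak-to-peak")
if report.phase:
    print(f"phase lag       : {report.phase.lag_s * 1000:.1f} ms "
          f"(peak correlation {report.phase.peak_correlation:.3f})")
print()
print("Both channels are driven by one cardiac waveform, so the recovered")
print("rates match exactly and the lag is at most one 20 ms sample.")
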