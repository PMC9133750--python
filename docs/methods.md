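# Methods

## Acquisition model

One hardware counter at the B-scan rate (default 50 Hz) synchronises both
channels. Per 20 ms cycle: the galvo waveform and the PPG sample trigger
fire at the cycle start; the laser/PA acquisition is delayed by a quarter
period, so the B-scan occupies the forward half-sweep [T/4, 3T/4) and the
PPG sample falls in the reverse sweep. Each cycle therefore yields exactly
one PA frame (timestamped at its window centre, T/2) and one PPG sample
(timestamped at the cycle start); the channels never overlap and carry a
fixed 10 ms intra-cycle offset that the cross-modal stage removes by
interpolating on true timestamps.

Grid geometry derives from the digitiser and the speed of sound: axial
pitch = c/(2·f_s) = 1540 m s⁻¹ / (2·500 MS/s) = 1.54 µm, 512 samples
(~0.79 mm depth); lateral pitch = scan range / A-lines per frame =
1000 µm / 200 = 5 µm. All µm↔pixel conversions go through these two
numbers (single source of truth in `AcquisitionConfig`).

## Synthetic scene

* **Cardiac waveform** `w(t)`: fundamental (default 1.35 Hz) plus decaying
  harmonics (1, 0.3, 0.1), normalised to unit peak-to-peak. The pulse
  shape is a generic stand-in — the analysis only recovers the
  fundamental. Optional heart-rate variability modulates the
  instantaneous frequency with cosine-smoothed Gaussian control points
  (1 s spacing, SD `hrv_sd_hz`), integrated into a continuous phase so
  that the frame and PPG channels, which sample at different instants,
  stay mutually coherent.
* **Vessels**: 2-D Gaussian blobs (σ = radius/2, default radius 20 µm —
  small digital vessels), five of them spread over 250–550 µm depth, all
  displaced by one shared motion signal
  `p2p·w(t) + drift(t)` — coherent pulsation is the default because the
  tracked vessels are observed to move with one pattern. The occluded
  scenario sets the motion amplitude and the PPG cardiac gain to zero
  while drift and noise persist.
* **Drift** (subject motion): a sub-1 Hz sinusoid (default 0.3 Hz,
  20 µm amplitude) plus a linear term (0.1 µm/s) — the minimal model
  producing the low-frequency spectral components the high-pass stage
  must remove.
* **Noise**: additive i.i.d. Gaussian per pixel. Image SNR is *defined*
  as peak vessel amplitude over noise SD and quoted in dB of that ratio:
  ratio = 10^(dB/10), so the default 10 dB puts the noise SD at one tenth
  of the vessel peak. (The i.i.d.-per-pixel model is harsher than real
  beamformed envelope noise, which is correlated at the PSF scale; at the
  default SNR the integer-pixel tracker's localisation jitter is ~2 µm
  RMS.) The PPG channel adds 10 mV Gaussian noise to a 1 V cardiac swing
  on a 2.5 V baseline and clips to [0, 5 V] (photodiode saturation).

What the generator does **not** model: speckle, acoustic wave propagation
and the system's finite resolution, lateral vessel motion, galvo inertia,
pulse-shape physiology. Passing recovery tests therefore demonstrate the
*algorithm chain* is correct and unbiased under the stated statistics, not
that real tissue meets those statistics.

## Vessel tracking

Per frame, the pixel with the maximum amplitude inside the vessel ROI
(default 64 axial × 32 lateral pixels ≈ 100 × 160 µm) is taken as the
vessel position; ties break to the smallest axial then lateral index for
determinism. The ROI re-centres on the previous maximum (clamped to the
frame) so slow drift cannot walk the vessel out of the box; a fixed-ROI
mode provides the strictly literal single-ROI variant. Localisation is
integer-pixel by design — the tracked quantity is *the pixel's* axial
position; a three-point parabolic sub-pixel refinement exists behind a
flag (default off). Tracks are de-meaned (removing each vessel's baseline
depth) and averaged point-wise; with five coherent vessels the averaged
trace correlates >0.99 with the generator's truth at default settings.

## Spectral analysis

Both channels are processed identically (symmetry keeps the heart-rate
comparison unbiased): zero-phase high-pass, then a Hann-tapered,
8×-zero-padded periodogram.

* **High-pass**: order-8 Butterworth, forward–backward (`sosfiltfilt`),
  design corner at 0.85× the nominal 1 Hz cutoff so that after squaring
  the response, ≥1.2 Hz loses <1 dB while ≤0.3 Hz loses >40 dB. Records
  shorter than one cutoff period are rejected.
* **Dominant frequency**: in-band (0.8–3 Hz ≙ 48–180 BPM) argmax of the
  padded periodogram; the 8× padding makes the read-out grid
  ≤(1/duration)/8 ≈ 2.1 mHz at 60 s, fine enough to distinguish 1.35 from
  1.40 Hz. Ties break to the lower frequency.
* **Displacement**: robust peak-to-peak = 98th − 2nd percentile of the
  high-passed motion trace (insensitive to isolated tracking outliers;
  plain max−min available behind a flag). For a pure sinusoid the
  percentile spread reads 99.8% of the true peak-to-peak; tracking jitter
  inflates it by roughly 1.8× its SD, which at default conditions keeps
  the estimate within ~6% of truth.
* **Pulsatility**: a channel is pulsatile when its dominant in-band peak
  power exceeds the *median* in-band power by ≥20. The threshold is
  calibrated on the null: the maximum of ~130 independent exponential
  periodogram ordinates in a 2.2 Hz band over 60 s reaches 8× the median
  in ~half of all noise records, but 20× in ~0.1%; the default therefore
  sits at 20 (<1% false positives at 60 s, measured over 3000 Monte Carlo
  draws), while genuinely pulsatile channels score 10³–10⁶.
* **Agreement**: heart rates "identical" is operationalised as dominant
  frequencies within one spectral grid bin (2.1 mHz at 60 s). Phase lag
  is the argmax of the normalised cardiac-band cross-correlation within
  ± one period, with the PPG sign-flipped first (systolic volume increase
  lowers reflectance; the polarity is config-flippable since it is a
  convention). Channel-wise pulsatility disagreements yield the verdict
  "discordant" — surfaced, never resolved silently.

## Photon transport

Standard MCML scheme: weighted packets, exponential steps with
µ_t = µ_a + µ_s, absorption by weight attenuation, Henyey–Greenstein
scattering, Fresnel reflection/refraction at every refractive-index
boundary, Russian roulette below weight 10⁻⁴ with survival 0.1 (weights
×10). Geometry is 3-D (pencil beam entering at the origin; optional
uniform-disk source) with a 2-D (x, z) tally projected along y: each
scattering site of a packet is buffered and, if the packet later exits the
top surface inside the detector disk (default radius 0.5 mm at 2 mm
offset) and acceptance cone, deposited into the visit-density grid.

The **characteristic sampling depth** is the mass quantile of the visit
column at the source–detector midpoint (where the co-aligned imaging beam
sits). The default quantile is 0.5 — half of the detected light's
interactions occur above this depth — which describes where the bulk of
detected light travels; higher quantiles (e.g. 0.9) describe the deep
tail of the banana instead and sit ~2.2× deeper for these profiles. Both
the quantile and the lateral position are configurable.

The bundled seven-layer model (stratum corneum → subcutaneous fat) uses
literature-typical green-light (532 nm) optical properties, marked as
external provenance in its docstring and fully overridable via
`SkinLayer` lists or a CSV model file. With it, the median sampling depth
at 2 mm separation is ≈0.67 mm, rising monotonically with separation
(≈0.41 mm at 1 mm, ≈0.85 mm at 3 mm), so a 3-candidate scan at a 0.67 mm
target selects 2 mm.

Validation is dual-route: the weighted walker matches (i) the exact
Chandrasekhar H-function reflectance for a semi-infinite
isotropic-scattering half-space (R = 0.41495 at ω = 0.9, matched
boundary) and (ii) an independent naive unweighted walker for the
anisotropic case (g = 0.75), both to Monte Carlo error; energy
(specular + diffuse + absorbed + transmitted) is conserved to 10⁻³ at
10⁵ packets, and the batch standard error scales as n^(−0.5).

## Reproducibility

Every random stage draws from a named substream (`waveform`, `frames`,
`ppg`, `mc`) of one top-level seed via `numpy.random.SeedSequence` spawn
keys, so stages can be re-run independently yet bit-identically; identical
(config, seed) pairs reproduce trials, reports and Monte Carlo tallies
exactly. Configs round-trip through YAML/JSON with dataclass equality.

## Problem sizes

Unit tests run on a quarter-size grid (256 × 64 pixels, 12–20 s records,
3 vessels); the batch recovery suites use 50 normal and 50 occluded 12 s
trials. The headline recovery checks and the acceptance script use the
full default geometry (512 × 200, 60 s, 5 vessels); the probe-design
check uses 10⁶ photon packets. The 12 s batch records keep the spectral
read-out grid at ~10 mHz, still an order of magnitude finer than the
±0.05 Hz recovery tolerance.

## Known limitations

* Integer-pixel localisation quantises positions to 1.54 µm; at very low
  motion amplitudes (≲5 µm p2p) quantisation dominates the spectrum.
* The pulsatility threshold is calibrated for ≥10 s records at 50 Hz;
  much longer records raise the noise maximum slowly (log n) and would
  warrant re-calibration.
* The phase-lag estimate is integer-sample (20 ms); sub-sample lags need
  the (not implemented) interpolated correlation peak.
* The seven-layer optical table is representative, not subject-specific;
  absolute sampling depths inherit its uncertainty, the monotone
  separation→depth trend does not.
* Occlusion is modelled as an exact null (zero cardiac gain); partial
  occlusions produce intermediate prominences the binary verdict maps to
  whichever side of the threshold they fall on.
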