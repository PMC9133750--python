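"""Choose the PPG source–detector slit distance by Monte Carlo.

Photons are launched into a seven-layer skin model; those that re-emerge
inside the photodiode aperture contribute their path to a visit-density
("banana") tally.  The depth profile of that tally in the column midway
between LED and photodiode — where the co-aligned imaging beam sits — gives
the characteristic sampling depth for each candidate slit distance; the
design goal is to match the imaging focus depth (~0.67 mm).
"""

from pampg import ProbeGeometry, launch_photons, optimal_separation, \
    sensitivity_depth_profile, seven_layer_skin

layers = seven_layer_skin()

choice = optimal_separation(layers, [1.0, 2.0, 3.0], target_depth_mm=0.67,
                            n_photons=150_000, seed=5)
print("separation scan (150k photons each):")
for row in choice.table:
    print(f"  {row['separation_mm']:.0f} mm slit → sampling depth "
          f"{row['depth_mm']:.2f} mm (detected weight {row['detected_weight']:.2e})")
print(f"chosen slit distance: {choice.chosen_separation_mm:.0f} mm "
      f"for a {choice.target_depth_mm} mm target\n")

res = launch_photons(layers, ProbeGeometry.from_mm(2.0), 300_000, seed=6)
prof = sensitivity_depth_profile(res)
print(f"at 2 mm: {res.n_detected} detected photons, "
      f"diffuse reflectance {res.diffuse_reflectance:.3f}")
print(f"median-mass sampling depth at the probe midpoint: "
      f"{prof.characteristic_depth_mm:.2f} mm")
print()
print("Larger slits force detected photons through deeper arcs, so the")
print("sampling depth grows with separation; 2 mm lands at the focus depth.")
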