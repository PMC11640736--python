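"""Detector-offset response and the positioning Type B uncertainty.

Scans the DAP per unit area of the calorimeter-core aperture (8.0 mm radius)
across horizontal offsets at y = -11 mm, then propagates a Gaussian
positioning model (+/-1 mm at 95%, sigma = 0.5 mm) through the offset
response to get the Type B dose uncertainty, for both measurement depths.
"""

from pmbdose import (MinibeamFieldSpec, PSPC_RADIUS, generate_minibeam_map,
                     horizontal_offset_scan, sample_type_b,
                     vertical_offset_scan)

spec = MinibeamFieldSpec()
for label, s in [("mono-energetic (2 cm WED)", spec),
                 ("SOBP depth (10 cm WED)", spec.sobp())]:
    dose_map = generate_minibeam_map(s)
    scan_h = horizontal_offset_scan(dose_map, PSPC_RADIUS)
    scan_v = vertical_offset_scan(dose_map, PSPC_RADIUS)
    at2 = float(scan_h.interpolator()(2.0))
    res = sample_type_b(scan_h, scan_v, n_samples=1_000_000, seed=1)
    print(f"{label}:")
    print(f"  normalized DAP at +2 mm offset: {at2:.4f} "
          f"({100 * (at2 - 1):+.2f}%)")
    print(f"  positioning Type B: horizontal {res.horizontal:.2f}%, "
          f"vertical {res.vertical:.2f}%, combined {res.combined:.2f}%")

print()
print("The SOBP-depth field is smoother (broader beamlets, deeper valley")
print("fill-in), so the same positioning tolerance costs much less dose")
print("uncertainty than at the mono-energetic depth.")
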