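"""Generate the default synthetic minibeam field and describe its structure.

The field emulates a planar proton minibeam pattern: 15 beamlets of 400 um
collimator width on a 4 mm pitch, 50 mm long, blurred laterally by 0.9 mm of
scatter at the measurement depth, over a 5% valley background.
"""

import numpy as np

from pmbdose import MinibeamFieldSpec, generate_minibeam_map

spec = MinibeamFieldSpec()
dose_map = generate_minibeam_map(spec)

row = dose_map.values[np.argmin(np.abs(dose_map.y_coords)), :]
x = dose_map.x_coords
peak = row[np.abs(x) < 0.5].max()
valley = row[np.abs(x - 2.0) < 0.5].min()

print(f"grid: {dose_map.shape[0]} x {dose_map.shape[1]} pixels at "
      f"{dose_map.pixel_spacing:.5f} mm (600 dpi)")
print(f"peak dose on the central beamlet:  {peak:.3f} Gy")
print(f"valley dose between beamlets:      {valley:.3f} Gy")
print(f"peak-to-valley dose ratio (PVDR):  {peak / valley:.2f}")
print()
print("The PVDR measures how sharply the field is spatially fractionated;")
print("it shrinks with depth as multiple Coulomb scattering broadens each")
print("beamlet (compare spec.sobp(), which models the SOBP depth).")
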