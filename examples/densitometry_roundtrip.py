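"""Phantom radiograph -> wedge calibration -> annual density/extension series.

Generates a noiseless slab phantom whose density alternates sinusoidally
(period 0.8 cm, mean 1.4 g cm^-3) along the growth axis, calibrates gray to
density through the stepped aragonite wedge, and recovers the annual bands.
The recovered table should match the planted truth to quantization error:
extensions of 0.80 cm and annual densities of 1.40 g cm^-3.
"""

import numpy as np

from coralcarb import densitometry as dens
from coralcarb import synthetic as syn

params = syn.RadiographPhantomParams(noise_sd=0.0)
rad, truth = syn.generate_radiograph(params, seed=42)

curve = dens.build_calibration(rad)
profile = dens.extract_density_profile(rad, curve, track_width=5)
bands = dens.detect_annual_bands(profile)

print("recovered annual bands:")
print(bands.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("planted truth: extensions", truth.band_extensions_cm,
      "densities", np.round(truth.band_densities, 4))
print()
print("max |density error| :", f"{np.abs(bands.densities - truth.band_densities).max():.4f}",
      "g cm^-3 (tolerance of the method: ~1 gray quantization step)")
print("max |extension error|:", f"{np.abs(bands.extensions - truth.band_extensions_cm).max():.4f}",
      "cm (1 px = 0.01 cm)")
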