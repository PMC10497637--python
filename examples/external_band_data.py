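"""Fit the density mixed model to a user-supplied band dataset.

The package's models run unchanged on measured annual-band tables, e.g. data
exported from a sclerochronology study.  Supply a CSV with columns
colony, species, status, zone, band_age, extension_cm, density (map your
column names accordingly); one model is fitted per species, and for species
with three status levels the pairwise contrasts are reported as well.
Results on external data are reported, not asserted: model-specification
details (random-effect structure, band-age coding) can shift the statistics.

Usage:
    python examples/external_band_data.py path/to/bands.csv
"""

import sys

import pandas as pd

from coralcarb import mixed_models as mm

if len(sys.argv) != 2:
    sys.exit(__doc__)

data = pd.read_csv(sys.argv[1], comment="#")
for species, sub in data.groupby("species"):
    if sub["status"].nunique() < 2 or sub.groupby("status")["colony"].nunique().min() < 2:
        print(f"{species}: not enough colonies per status, skipped")
        continue
    fit = mm.fit_density_lmm(sub)
    print(f"\n== {species} ({sub['colony'].nunique()} colonies, {len(sub)} bands)")
    for w in mm.wald_type2(fit):
        print(f"  {w.term:45s} chi2={w.statistic:8.2f} df={w.df} p={w.p_value:.3g}")
    if len(fit.status_levels) == 3:
        for c in mm.pairwise_status_contrasts(fit):
            print(f"  {c.level_a} - {c.level_b}: est={c.estimate:+.3f} "
                  f"z={c.z:+.2f} p={c.p_value:.3g}")
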