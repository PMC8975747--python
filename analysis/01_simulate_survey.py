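#!/usr/bin/env python
"""Simulate the default multi-cruise survey and its ground truth.

Writes the canonical transect table, the truth sidecar, and a set of CTD
profiles; prints the headline properties of the generated section (ranges of
temperature, hosts and cyanophages) so later steps can be read in context.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cyanotransect import schema
from cyanotransect.synthetic import TransectScenario, generate_ctd_profile, generate_transect

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

scenario = TransectScenario(seed=1)
samples, truth = generate_transect(scenario)
samples.to_csv(OUT / "transect.csv", index=False)
truth.table.to_csv(OUT / "transect_truth.csv", index=False)
with open(OUT / "truth_meta.json", "w") as fh:
    json.dump(
        {
            "hotspot_center_c": truth.hotspot_center_c,
            "hotspot_width_c": truth.hotspot_width_c,
            "hotspot_range_c": truth.hotspot_range_c,
            "regression_truth": truth.regression_truth,
            "infection_link": truth.infection_link,
        },
        fh, indent=2)

# a few CTD stations per regime for the mixed-layer step
rng = np.random.default_rng(scenario.seed + 1)
profiles = []
for regime, mld in [("subtropical", 60.0), ("transition", 40.0), ("subpolar", 30.0)]:
    for station in range(5):
        depths, density = generate_ctd_profile(mld + rng.normal(0, 5), seed=rng)
        profiles.append(pd.DataFrame({
            "regime": regime, "station": f"{regime}_{station}",
            "depth_m": depths, "potential_density_kg_m3": density}))
pd.concat(profiles, ignore_index=True).to_csv(OUT / "ctd_profiles.csv", index=False)

print(f"survey: {len(samples)} samples on {samples[schema.CRUISE].nunique()} cruises")
print(f"temperature {samples[schema.TEMP].min():.1f}-{samples[schema.TEMP].max():.1f} C, "
      f"salinity {samples[schema.SAL].min():.2f}-{samples[schema.SAL].max():.2f}")
print(f"Prochlorococcus up to {samples[schema.PRO].max():.3g} ml^-1; "
      f"cyanophages {samples[schema.PHAGE_TOTAL].min():.3g}-"
      f"{samples[schema.PHAGE_TOTAL].max():.3g} ml^-1")
print(f"wrote {OUT/'transect.csv'}, truth sidecar, and 15 CTD profiles")
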