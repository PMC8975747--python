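#!/usr/bin/env python
"""Classify the survey into oceanic regimes, locate the chlorophyll front,
and compute mixed-layer depths from the CTD stations."""

from pathlib import Path

import pandas as pd

from cyanotransect import schema
from cyanotransect.regimes import annotate_regimes, chlorophyll_front, mixed_layer_depth

OUT = Path(__file__).resolve().parents[1] / "results"
samples = pd.read_csv(OUT / "transect.csv")

annotated = annotate_regimes(samples)
annotated.to_csv(OUT / "transect_regimes.csv", index=False)
print(annotated[schema.REGIME].value_counts().to_string())

for cruise, g in annotated.groupby(schema.CRUISE):
    front = chlorophyll_front(g[schema.LAT], g[schema.CHL])
    print(f"{cruise}: 0.2 mg m^-3 chlorophyll front at "
          f"{front:.2f} deg N" if front else f"{cruise}: no front crossing")

ctd = pd.read_csv(OUT / "ctd_profiles.csv")
mld_rows = []
for (regime, station), prof in ctd.groupby(["regime", "station"]):
    mld = mixed_layer_depth(prof["depth_m"], prof["potential_density_kg_m3"])
    mld_rows.append({"regime": regime, "station": station, "mld_m": mld})
mld_df = pd.DataFrame(mld_rows)
mld_df.to_csv(OUT / "mixed_layer_depths.csv", index=False)
print("mean mixed-layer depth by regime (m):")
print(mld_df.groupby("regime")["mld_m"].mean().round(1).to_string())
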