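#!/usr/bin/env python
"""Convert instantaneous infection to daily and per-generation virus-mediated
mortality along the survey."""

import json
from pathlib import Path

import pandas as pd

from cyanotransect import schema
from cyanotransect.mortality import annotate_mortality

OUT = Path(__file__).resolve().parents[1] / "results"
df = pd.read_csv(OUT / "transect_regimes.csv")
hot = json.loads((OUT / "hotspot.json").read_text())

dm = annotate_mortality(df)
dm.to_csv(OUT / "transect_mortality.csv", index=False)

band = dm[(dm[schema.TEMP] >= hot["t_lo_c"]) & (dm[schema.TEMP] <= hot["t_hi_c"])]
sub = dm[dm[schema.REGIME] == "subtropical"]
for host in schema.HOSTS:
    md = schema.mortality_col("daily", host)
    mg = schema.mortality_col("generation", host)
    print(f"{host}: subtropical daily mortality {100*sub[md].mean():.1f}% (mean), "
          f"hotspot peak {100*band[md].max():.1f}%; "
          f"per-generation peak {100*band[mg].max():.1f}%")
print(f"wrote {OUT/'transect_mortality.csv'}")
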