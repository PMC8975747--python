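#!/usr/bin/env python
"""Budget virus-released organic carbon against bacterial carbon demand per
regime, using the CTD-derived mixed-layer depths."""

from pathlib import Path

import pandas as pd

from cyanotransect import schema
from cyanotransect.biogeochem import dom_comparison, regime_budget
from cyanotransect.pipeline import DEFAULT_AREAS_KM2

OUT = Path(__file__).resolve().parents[1] / "results"
dm = pd.read_csv(OUT / "transect_mortality.csv")
mld = pd.read_csv(OUT / "mixed_layer_depths.csv").groupby("regime")["mld_m"].mean().to_dict()

budget = regime_budget(dm, DEFAULT_AREAS_KM2, mld)
budget.to_csv(OUT / "carbon_budget.csv", index=False)

cols = ["lysate_c_umol_l_d", "bacterial_production_umol_l_d", "fraction_bcd_sustained",
        "total_lysate_c_g_d"]
print(budget.set_index(schema.REGIME)[cols].round(5).to_string())
for _, row in budget.iterrows():
    ratios = dom_comparison({"c": row["lysate_c_umol_l_d"],
                             "n": row["lysate_n_umol_l_d"],
                             "p": row["lysate_p_umol_l_d"]})
    print(f"{row[schema.REGIME]}: lysate / reported DOM production = "
          f"C {ratios['c']:.2f}, N {ratios['n']:.2f}, P {ratios['p']:.2f}")
print(f"wrote {OUT/'carbon_budget.csv'}")
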