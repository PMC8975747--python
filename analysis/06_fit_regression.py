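#!/usr/bin/env python
"""Fit the temperature x chlorophyll regression on the survey, screen the
candidate predictor sets on an independent validation cruise, and apply the
deployment model to a small gridded field."""

from pathlib import Path

import numpy as np
import pandas as pd

from cyanotransect import schema
from cyanotransect.regression import fit_model, grid_predict, train_test_evaluate
from cyanotransect.synthetic import TransectScenario, default_chlorophyll, default_temperature, generate_transect

OUT = Path(__file__).resolve().parents[1] / "results"
train = pd.read_csv(OUT / "transect_regimes.csv")

# independent validation cruise (later year, single out-and-back section)
validation, _ = generate_transect(TransectScenario(seed=19, cruise_ids=("KM19",), n_samples=24))
ranking = train_test_evaluate(train, validation)
ranking.to_csv(OUT / "model_selection.csv", index=False)
print("candidate ranking by validation RMSE (log10 viruses ml^-1):")
print(ranking[["rank", "candidate", "rmse_train", "rmse_test"]].round(4).to_string(index=False))

model = fit_model(train)
model.to_json(OUT / "model.json")
se = model.standard_errors()
print("deployment model log10(V) = k0 + k1*T + k2*Chl + k3*T*Chl:")
for name, k, s in zip(model.feature_names, model.coefficients, se):
    print(f"  {name}: {k:+.4f} +/- {s:.4f}")

# small gridded application with the validity mask
lat = np.linspace(20, 50, 61)
lon_cells = 40
T = np.tile(default_temperature(lat)[:, None], (1, lon_cells))
C = np.tile(default_chlorophyll(lat)[:, None], (1, lon_cells))
grid = grid_predict({"total": model}, T, C)
np.savetxt(OUT / "grid_prediction.csv", grid.predicted["total"], delimiter=",")
print(f"gridded prediction: {grid.valid.sum()} of {grid.valid.size} cells valid "
      f"(mask: T > 5 C and Chl < 0.4 mg m^-3)")
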