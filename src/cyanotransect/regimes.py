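"""Oceanic regime classification, chlorophyll front, and mixed-layer depth.

Regimes follow the classical salinity thresholds for the North Pacific:
subtropical gyre water is saltier than 34.6, subpolar water fresher than 33,
and the intermediate band is the transition zone.  The chlorophyll front is
the 0.2 mg m^-3 surface-chlorophyll contour; the mixed layer is the depth at
which surface-referenced potential density first exceeds the surface value by
0.1 kg m^-3.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import schema

SUBTROPICAL_SALINITY = 34.6
SUBPOLAR_SALINITY = 33.0
FRONT_CHL = 0.2
MLD_DENSITY_THRESHOLD = 0.1

__all__ = [
    "classify_regime",
    "classify_regimes",
    "chlorophyll_front",
    "mixed_layer_depth",
    "annotate_regimes",
]


def classify_regime(salinity: float) -> str:
    """Regime label for one salinity value.

    Boundary values (exactly 34.6 or 33.0) are "intermediate waters" and fall
    in the transition zone (closed interval).  Missing salinity -> "unlabelled".
    """
    if salinity is None or (isinstance(salinity, float) and np.isnan(salinity)):
        warnings.warn("missing salinity; sample left unlabelled", stacklevel=2)
        return "unlabelled"
    if not 0 <= salinity <= 45:
        raise ValueError(f"salinity {salinity} outside the physically plausible 0-45 PSU")
    if salinity > SUBTROPICAL_SALINITY:
        return "subtropical"
    if salinity < SUBPOLAR_SALINITY:
        return "subpolar"
    return "transition"


def classify_regimes(salinity) -> np.ndarray:
    """Vectorized :func:`classify_regime` (NaN -> "unlabelled", no warning spam)."""
    sal = np.asarray(salinity, dtype=float)
    if np.any((sal < 0) | (sal > 45)):
        raise ValueError("salinity outside the physically plausible 0-45 PSU")
    out = np.full(sal.shape, "transition", dtype=object)
    out[sal > SUBTROPICAL_SALINITY] = "subtropical"
    out[sal < SUBPOLAR_SALINITY] = "subpolar"
    out[np.isnan(sal)] = "unlabelled"
    return out


def chlorophyll_front(latitudes, chlorophyll, threshold: float = FRONT_CHL) -> float | None:
    """Latitude of the chlorophyll front (first south-to-north upward crossing).

    Linear interpolation between the bracketing samples.  Returns ``None``
    when all values sit on one side of the threshold; if several upward
    crossings exist the southernmost is used and a warning is emitted.
    """
    lats = np.asarray(latitudes, dtype=float)
    chl = np.asarray(chlorophyll, dtype=float)
    if lats.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(chl < 0):
        raise ValueError("chlorophyll must be >= 0")
    order = np.argsort(lats)
    lats, chl = lats[order], chl[order]
    below = chl[:-1] < threshold
    above = chl[1:] >= threshold
    crossings = np.flatnonzero(below & above)
    if crossings.size == 0:
        return None
    if crossings.size > 1:
        warnings.warn(
            f"{crossings.size} upward chlorophyll crossings; using the southernmost",
            stacklevel=2,
        )
    i = crossings[0]
    frac = (threshold - chl[i]) / (chl[i + 1] - chl[i])
    return float(lats[i] + frac * (lats[i + 1] - lats[i]))


def mixed_layer_depth(depth, density, threshold: float = MLD_DENSITY_THRESHOLD) -> float | None:
    """Mixed-layer depth (m) from a potential-density profile.

    Linearly interpolated depth where density first exceeds the surface value
    by ``threshold``; ``None`` when the profile never does ("MLD deeper than
    profile").
    """
    z = np.asarray(depth, dtype=float)
    rho = np.asarray(density, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 profile levels")
    if np.any(np.diff(z) <= 0):
        raise ValueError("depth must be strictly increasing")
    target = rho[0] + threshold
    exceed = np.flatnonzero(rho > target)
    if exceed.size == 0:
        return None
    j = exceed[0]
    if j == 0:
        return float(z[0])
    frac = (target - rho[j - 1]) / (rho[j] - rho[j - 1])
    return float(z[j - 1] + frac * (z[j] - z[j - 1]))


def annotate_regimes(df: pd.DataFrame, front_per_cruise: bool = True) -> pd.DataFrame:
    """Add regime and north-of-front columns to a transect table.

    The front is located per cruise (cruises differ in front position); samples
    on a cruise without a crossing get ``north_of_front = False``.
    """
    if schema.SAL not in df.columns:
        raise KeyError(f"missing required column {schema.SAL!r}")
    out = df.copy()
    out[schema.REGIME] = classify_regimes(out[schema.SAL].to_numpy())
    north = np.zeros(len(out), dtype=bool)
    groups = out.groupby(schema.CRUISE) if front_per_cruise else [(None, out)]
    for _, g in groups:
        front = chlorophyll_front(g[schema.LAT].to_numpy(), g[schema.CHL].to_numpy())
        if front is not None:
            north[out.index.get_indexer(g.index)] = g[schema.LAT].to_numpy() > front
    out[schema.NORTH_OF_FRONT] = north
    return out
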