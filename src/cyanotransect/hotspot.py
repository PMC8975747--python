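"""Detection of the cyanophage hotspot on the temperature axis.

The hotspot is located where the rate of change of cyanophage abundance with
temperature is most rapid.  The procedure: (1) scale abundances to each
cruise-wide maximum and centre on the mean scaled subtropical abundance;
(2) interpolate the pooled profile onto a regular temperature grid and smooth
with a 2.5 °C sliding window; (3) take the second derivative with respect to
temperature; (4) the largest positive-curvature peak on each flank of the
smoothed abundance maximum defines the temperature edges of the hotspot, which
are then mapped to latitude per cruise through each cruise's monotone
temperature–latitude relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from scipy.stats import pearsonr

from . import schema

__all__ = [
    "scale_and_center",
    "smooth_by_temperature",
    "curvature",
    "detect_hotspot",
    "temperature_to_latitude",
    "regime_correlation",
    "HotspotResult",
    "hotspot_from_transect",
]


def scale_and_center(
    df: pd.DataFrame,
    abundance_col: str = schema.PHAGE_TOTAL,
    cruise_col: str = schema.CRUISE,
    regime_col: str = schema.REGIME,
) -> pd.DataFrame:
    """Per-cruise scaling to the cruise maximum, then subtropical centring.

    Returns a copy with ``phage_scaled`` (x / cruise max, so the cruise-wise
    maximum is 1) and ``phage_centered`` (scaled minus the cruise's mean scaled
    subtropical abundance).  A cruise with no subtropical samples or a
    non-positive maximum is an error naming the cruise.
    """
    out = df.copy()
    scaled = np.empty(len(out))
    centered = np.empty(len(out))
    for cruise, g in out.groupby(cruise_col):
        x = g[abundance_col].to_numpy(dtype=float)
        mx = np.nanmax(x)
        if not mx > 0:
            raise ValueError(f"cruise {cruise!r} has no positive abundance maximum")
        sub = g[regime_col] == "subtropical"
        if not sub.any():
            raise ValueError(f"cruise {cruise!r} has no subtropical samples to centre on")
        s = x / mx
        idx = out.index.get_indexer(g.index)
        scaled[idx] = s
        centered[idx] = s - s[sub.to_numpy()].mean()
    out[schema.SCALED] = scaled
    out[schema.CENTERED] = centered
    return out


def smooth_by_temperature(
    temperature,
    values,
    window: float = 2.5,
    grid_step: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean on a regular temperature grid.

    Irregular samples are first interpolated to a ``grid_step`` grid
    (duplicate temperatures averaged), then averaged over a window of total
    width ``window``; endpoints use the truncated window.
    """
    t = np.asarray(temperature, dtype=float)
    v = np.asarray(values, dtype=float)
    if window <= 0:
        raise ValueError("window must be > 0")
    if t.size < 5:
        raise ValueError("need at least 5 samples")
    span = t.max() - t.min()
    if span <= window:
        raise ValueError(f"temperature span {span:.2f} must exceed the window {window}")
    # reduce samples to per-bin means at their mean temperature (exact for
    # affine profiles, and averages replicate noise before interpolation)
    order = np.argsort(t)
    ts, vs = t[order], v[order]
    bins = np.round((ts - ts[0]) / grid_step).astype(int)
    _, inverse = np.unique(bins, return_inverse=True)
    cnts = np.bincount(inverse)
    t_mean = np.bincount(inverse, weights=ts) / cnts
    v_mean = np.bincount(inverse, weights=vs) / cnts
    grid = np.arange(ts[0], ts[-1] + grid_step / 2, grid_step)
    interp = np.interp(grid, t_mean, v_mean)
    half_bins = int(round(window / 2 / grid_step))
    csum = np.concatenate([[0.0], np.cumsum(interp)])
    n = grid.size
    lo = np.clip(np.arange(n) - half_bins, 0, n)
    hi = np.clip(np.arange(n) + half_bins + 1, 0, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return grid, smoothed


def curvature(values, grid_step: float, stencil_bins: int = 1) -> np.ndarray:
    """Second derivative on a regular grid by central finite differences.

    ``(f[i-k] - 2 f[i] + f[i+k]) / (k*dt)^2`` with ``k = stencil_bins``;
    the ``k`` entries at each end are undefined and returned as NaN.  A wider
    stencil trades resolution for noise suppression.
    """
    f = np.asarray(values, dtype=float)
    k = int(stencil_bins)
    if f.size < 2 * k + 1 or f.size < 3:
        raise ValueError("grid too short for the requested stencil")
    if k < 1:
        raise ValueError("stencil_bins must be >= 1")
    out = np.full(f.size, np.nan)
    h = k * grid_step
    out[k:-k] = (f[:-2 * k] - 2 * f[k:-k] + f[2 * k:]) / h**2
    return out


@dataclass
class HotspotResult:
    """Detected hotspot: temperature edges plus the diagnostic curves."""

    found: bool
    t_lo: float | None
    t_hi: float | None
    t_peak: float | None
    grid: np.ndarray
    smoothed: np.ndarray
    curvature: np.ndarray
    flags: list[str] = field(default_factory=list)
    lat_ranges: dict = field(default_factory=dict)


def _boxcar(values: np.ndarray, half_bins: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(values)])
    n = values.size
    lo = np.clip(np.arange(n) - half_bins, 0, n)
    hi = np.clip(np.arange(n) + half_bins + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def detect_hotspot(
    temperature,
    values,
    window: float = 2.5,
    grid_step: float = 0.1,
    curvature_step: float | None = None,
    curvature_smooth: float | None = None,
) -> HotspotResult:
    """Locate the hotspot's temperature range from a pooled profile.

    The smoothed-profile maximum must be interior (a monotone profile has no
    hotspot).  Edges are the temperatures of the largest positive-curvature
    peak on the cold and warm flanks of that maximum; ties are broken toward
    the peak.  ``curvature_step`` (°C) sets the differencing stencil; the
    default ``window/2`` suppresses grid-scale noise.
    """
    grid, smoothed = smooth_by_temperature(temperature, values, window, grid_step)
    step_c = window / 2 if curvature_step is None else curvature_step
    k = max(1, int(round(step_c / grid_step)))
    if grid.size < 2 * k + 3:
        raise ValueError("profile too short for curvature estimation")
    curv = curvature(smoothed, grid_step, stencil_bins=k)
    smooth_c = window if curvature_smooth is None else curvature_smooth
    if smooth_c > 0:
        # the curvature diagnostic itself is averaged before peak-picking:
        # flank peaks are broad and shallow, so unsmoothed argmax is noise-limited
        valid = ~np.isnan(curv)
        curv[valid] = _boxcar(curv[valid], int(round(smooth_c / 2 / grid_step)))
    imax = int(np.argmax(smoothed))
    flags: list[str] = []
    # interior test: the abundance maximum must clear the undefined edge zones
    if imax <= k or imax >= grid.size - 1 - k:
        return HotspotResult(False, None, None, None, grid, smoothed, curv,
                             flags=["no_interior_maximum"])
    t_peak = float(grid[imax])

    def flank_edge(side: str) -> float:
        if side == "cold":
            idx = np.arange(k, imax)
        else:
            idx = np.arange(imax + 1, grid.size - k)
        c = curv[idx]
        pos = c > 0
        if not pos.any():
            flags.append(f"no_positive_curvature_{side}")
            return float(grid[idx[0] if side == "cold" else idx[-1]])
        cmax = c[pos].max()
        # ties broken toward the abundance peak
        cand = idx[pos & np.isclose(c, cmax, rtol=1e-12, atol=0.0)]
        j = cand[-1] if side == "cold" else cand[0]
        return float(grid[j])

    t_lo = flank_edge("cold")
    t_hi = flank_edge("warm")
    return HotspotResult(True, t_lo, t_hi, t_peak, grid, smoothed, curv, flags=flags)


def temperature_to_latitude(
    t_range: tuple[float, float],
    cruise_df: pd.DataFrame,
    median_filter: int = 3,
) -> tuple[float, float, list[str]]:
    """Map a temperature range onto one cruise's latitude axis.

    The cruise's temperature–latitude relation is median-filtered to remove
    small inversions and forced monotone (non-increasing northward) before
    inversion.  Boundary temperatures outside the cruise's observed range clip
    to the transect ends with a flag.  Returns (lat_lo, lat_hi, flags) with
    lat_lo <= lat_hi.
    """
    g = cruise_df.sort_values(schema.LAT)
    lats = g[schema.LAT].to_numpy(dtype=float)
    temps = g[schema.TEMP].to_numpy(dtype=float)
    if lats.size >= median_filter:
        temps = medfilt(temps, kernel_size=median_filter)
    temps = np.minimum.accumulate(temps)  # enforce monotone decrease northward
    flags: list[str] = []
    t_cold, t_warm = sorted(t_range)
    lat_for = {}
    for name, t in (("warm", t_warm), ("cold", t_cold)):
        if t > temps[0]:
            flags.append(f"{name}_edge_clipped_south")
            lat_for[name] = lats[0]
        elif t < temps[-1]:
            flags.append(f"{name}_edge_clipped_north")
            lat_for[name] = lats[-1]
        else:
            # interpolate on the reversed (increasing) temperature axis
            lat_for[name] = float(np.interp(t, temps[::-1], lats[::-1]))
    lat_lo, lat_hi = sorted((lat_for["warm"], lat_for["cold"]))
    return lat_lo, lat_hi, flags


def regime_correlation(x, y) -> tuple[float, float, int]:
    """Pearson correlation of log10-transformed abundances.

    Pairs with non-positive or missing values are dropped (log undefined).
    Returns (r, two-sided p, n); zero-variance input is flagged as NaN.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = np.isfinite(xa) & np.isfinite(ya) & (xa > 0) & (ya > 0)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 valid pairs")
    lx, ly = np.log10(xa[ok]), np.log10(ya[ok])
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    r, p = pearsonr(lx, ly)
    return float(r), float(p), n


def hotspot_from_transect(
    df: pd.DataFrame,
    abundance_col: str = schema.PHAGE_TOTAL,
    window: float = 2.5,
    grid_step: float = 0.1,
    per_cruise_smoothing: bool = False,
) -> HotspotResult:
    """Scale/centre, pool, detect, and map the hotspot to latitude per cruise.

    By default the 2.5 °C smoothing runs on the pooled centred samples from all
    cruises; ``per_cruise_smoothing`` averages per-cruise detections instead.
    """
    scaled = scale_and_center(df, abundance_col=abundance_col)
    if per_cruise_smoothing:
        edges = []
        for _, g in scaled.groupby(schema.CRUISE):
            res = detect_hotspot(g[schema.TEMP], g[schema.CENTERED], window, grid_step)
            if res.found:
                edges.append((res.t_lo, res.t_hi))
        if not edges:
            return HotspotResult(False, None, None, None, np.array([]), np.array([]),
                                 np.array([]), flags=["no_hotspot_any_cruise"])
        t_lo = float(np.mean([e[0] for e in edges]))
        t_hi = float(np.mean([e[1] for e in edges]))
        result = detect_hotspot(scaled[schema.TEMP], scaled[schema.CENTERED], window, grid_step)
        result.t_lo, result.t_hi = t_lo, t_hi
    else:
        result = detect_hotspot(scaled[schema.TEMP], scaled[schema.CENTERED], window, grid_step)
    if result.found:
        for cruise, g in scaled.groupby(schema.CRUISE):
            lat_lo, lat_hi, flags = temperature_to_latitude((result.t_lo, result.t_hi), g)
            result.lat_ranges[cruise] = (lat_lo, lat_hi)
            result.flags += [f"{cruise}:{f}" for f in flags]
    return result
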