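"""Virus-mediated mortality from instantaneous infection measurements.

An instantaneous infected fraction I is converted to a daily loss rate by
multiplying by the number of infection cycles a cyanophage can complete in
24 h, and to a per-generation loss through the cumulative distribution
function M = 1 - exp(-M_daily * t_double): the expected fraction of the host
population infected and killed before it divides.

Cycle counts derive from culture latent periods (referenced to 21 °C),
corrected for temperature (latent period lengthens 25% per 3 °C of cooling,
and shortens symmetrically on warming), for light (latent periods are 40% of
their low-light value at the high irradiances of the surface mixed layer),
and for day length (no lysis at night).  Host division rates come from the
faster-growing ecotype at each temperature: high-light II *Prochlorococcus*
above 14.7 °C (high-light I below), and *Synechococcus* clade II above 23 °C
(clade I below).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import schema

__all__ = [
    "LineageParams",
    "HostParams",
    "DEFAULT_LINEAGES",
    "DEFAULT_HOSTS",
    "latent_period",
    "cycles_per_day",
    "daily_mortality",
    "generation_mortality",
    "doubling_time",
    "annotate_mortality",
]

REFERENCE_TEMP_C = 21.0
LATENT_FACTOR_PER_3C = 1.25
LIGHT_SHORTENING = 0.4  # high-light latent period as a fraction of the culture value


@dataclass(frozen=True)
class LineageParams:
    """Infection traits of one cyanophage lineage (culture-derived config)."""

    name: str
    latent_period_ref_h: float  # at 21 °C
    burst_size: float           # virions per lysed cell
    virion_carbon_fg: float     # fg C per particle

    def __post_init__(self) -> None:
        if self.latent_period_ref_h <= 0:
            raise ValueError("latent_period_ref_h must be > 0")
        if self.burst_size < 1:
            raise ValueError("burst_size must be >= 1")


@dataclass(frozen=True)
class HostParams:
    """Growth and stoichiometry traits of one picocyanobacterial host.

    ``doubling_warm_d``/``doubling_cold_d`` are constant per-ecotype doubling
    times used when no parametric ``ecotype_curves`` (temperature -> doubling
    time, days) are supplied.  Quotas and elemental ratios are configuration
    placeholders, not assertions.
    """

    taxon: str
    ecotype_threshold_c: float
    doubling_warm_d: float
    doubling_cold_d: float
    carbon_quota_fg: float
    c_to_p: float
    n_to_p: float
    temp_range_c: tuple[float, float] = (-2.0, 35.0)
    ecotype_curves: tuple[Callable[[float], float], ...] | None = None

    def __post_init__(self) -> None:
        if self.doubling_warm_d <= 0 or self.doubling_cold_d <= 0:
            raise ValueError("doubling times must be > 0")


DEFAULT_LINEAGES: dict[str, LineageParams] = {
    "t4": LineageParams("t4", latent_period_ref_h=9.0, burst_size=40, virion_carbon_fg=0.20),
    "t7b": LineageParams("t7b", latent_period_ref_h=6.0, burst_size=100, virion_carbon_fg=0.05),
    "t7a": LineageParams("t7a", latent_period_ref_h=5.0, burst_size=150, virion_carbon_fg=0.05),
    "tim5": LineageParams("tim5", latent_period_ref_h=8.0, burst_size=30, virion_carbon_fg=0.20),
}

DEFAULT_HOSTS: dict[str, HostParams] = {
    "pro": HostParams("pro", ecotype_threshold_c=14.7, doubling_warm_d=1.5,
                      doubling_cold_d=2.8, carbon_quota_fg=50.0, c_to_p=208.0, n_to_p=6.4),
    "syn": HostParams("syn", ecotype_threshold_c=23.0, doubling_warm_d=0.8,
                      doubling_cold_d=1.1, carbon_quota_fg=150.0, c_to_p=130.7, n_to_p=7.6),
}


def latent_period(
    temperature_c,
    params: LineageParams,
    correct_temperature: bool = True,
    warm_mode: str = "divide",
):
    """Latent period (h) at a given temperature.

    Lengthening on cooling is x1.25 per 3 °C below 21 °C; on warming the
    default is the symmetric multiplicative factor (division by 1.25 per
    3 °C).  ``warm_mode="multiply075"`` applies x0.75 per 3 °C instead.
    """
    t = np.asarray(temperature_c, dtype=float)
    if np.any((t < -2) | (t > 35)):
        raise ValueError("temperature outside the supported -2 to 35 °C range")
    if not correct_temperature:
        return np.broadcast_to(params.latent_period_ref_h, t.shape).astype(float) \
            if t.shape else float(params.latent_period_ref_h)
    if warm_mode == "divide":
        lp = params.latent_period_ref_h * LATENT_FACTOR_PER_3C ** ((REFERENCE_TEMP_C - t) / 3.0)
    elif warm_mode == "multiply075":
        cold = params.latent_period_ref_h * LATENT_FACTOR_PER_3C ** (
            np.clip(REFERENCE_TEMP_C - t, 0, None) / 3.0)
        warm = params.latent_period_ref_h * 0.75 ** (np.clip(t - REFERENCE_TEMP_C, 0, None) / 3.0)
        lp = np.where(t <= REFERENCE_TEMP_C, cold, warm)
    else:
        raise ValueError(f"unknown warm_mode {warm_mode!r}")
    return float(lp) if np.isscalar(temperature_c) else lp


def cycles_per_day(
    temperature_c,
    daylight_hours,
    params: LineageParams,
    light_shortening: float = LIGHT_SHORTENING,
    nocturnal_lysis: bool = False,
    correct_temperature: bool = True,
    floor: bool = False,
):
    """Infection cycles completable per day.

    cycles = available hours / (light_shortening x latent period), where the
    available hours are the daylight hours (no lysis at night) unless
    ``nocturnal_lysis`` extends lysis around the clock.  Continuous by
    default; ``floor`` truncates to whole cycles.
    """
    d = np.asarray(daylight_hours, dtype=float)
    if np.any((d < 0) | (d > 24)):
        raise ValueError("daylight_hours must be in [0, 24]")
    lp = latent_period(temperature_c, params, correct_temperature=correct_temperature)
    hours = np.full_like(d, 24.0) if nocturnal_lysis else d
    c = hours / (light_shortening * np.asarray(lp, dtype=float))
    if floor:
        c = np.floor(c)
    return float(c) if np.isscalar(daylight_hours) and np.isscalar(temperature_c) else c


def daily_mortality(instantaneous_infection, cycles):
    """Daily loss fraction: I x cycles per day, capped at 1."""
    i = np.asarray(instantaneous_infection, dtype=float)
    if np.any((i < 0) | (i > 1)):
        raise ValueError("instantaneous infection must be in [0, 1]")
    m = np.minimum(1.0, i * np.asarray(cycles, dtype=float))
    return float(m) if m.ndim == 0 else m


def generation_mortality(m_daily, doubling_time_d, convention: str = "specific-rate"):
    """Per-generation mortality M = 1 - exp(-M_daily x ln2 / mu).

    Under the default convention mu is the specific division rate with
    ln(2)/mu equal to the doubling time in days, so the exponent is
    M_daily x doubling_time.  The alternative reading (mu as doublings per
    day) multiplies the exponent by ln 2 and is selectable.
    """
    m = np.asarray(m_daily, dtype=float)
    td = np.asarray(doubling_time_d, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("daily mortality must be in [0, 1]")
    if np.any(td <= 0):
        raise ValueError("doubling time must be > 0")
    if convention == "specific-rate":
        expo = m * td
    elif convention == "doublings-per-day":
        expo = m * np.log(2.0) * td
    else:
        raise ValueError(f"unknown convention {convention!r}")
    out = 1.0 - np.exp(-expo)
    return float(out) if out.ndim == 0 else out


def doubling_time(temperature_c, host: HostParams):
    """Host doubling time (days): the faster-growing ecotype at each temperature.

    With parametric ecotype curves the pointwise minimum over curves is
    returned; with the constant defaults the ecotype is selected by the
    thermal threshold (warm ecotype strictly above it).
    """
    t = np.asarray(temperature_c, dtype=float)
    lo, hi = host.temp_range_c
    if np.any((t < lo) | (t > hi)):
        raise ValueError(f"temperature outside the supported range {host.temp_range_c}")
    if host.ecotype_curves:
        vals = np.minimum.reduce([np.asarray([c(x) for x in np.atleast_1d(t)])
                                  for c in host.ecotype_curves])
        out = vals if t.shape else float(vals[0])
        return out
    out = np.where(t > host.ecotype_threshold_c, host.doubling_warm_d, host.doubling_cold_d)
    return float(out) if out.ndim == 0 else out


def annotate_mortality(
    df: pd.DataFrame,
    lineages: Mapping[str, LineageParams] = DEFAULT_LINEAGES,
    hosts: Mapping[str, HostParams] = DEFAULT_HOSTS,
    daylight_hours: float | None = None,
    mu_convention: str = "specific-rate",
) -> pd.DataFrame:
    """Append per-lineage and total mortality columns to a transect table.

    Daily mortality of a host is the sum over lineages of that lineage's
    instantaneous infected fraction times its own cycles-per-day (each lineage
    completes cycles at its own latent period), capped at 1.  Daylight hours
    come from the table's column unless overridden.
    """
    out = df.copy()
    temp = out[schema.TEMP].to_numpy(dtype=float)
    if daylight_hours is not None:
        day = np.full(len(out), float(daylight_hours))
    elif schema.DAYLIGHT in out.columns:
        day = out[schema.DAYLIGHT].to_numpy(dtype=float)
    else:
        raise KeyError(f"no {schema.DAYLIGHT!r} column and no daylight_hours override")
    for host_key, host in hosts.items():
        total_daily = np.zeros(len(out))
        for lin in schema.HOST_LINEAGES[host_key]:
            col = schema.infected_col(host_key, lin)
            if col not in out.columns or lin not in lineages:
                continue
            cyc = cycles_per_day(temp, day, lineages[lin])
            m_lin = daily_mortality(out[col].to_numpy(dtype=float), cyc)
            out[schema.mortality_col("daily", host_key, lin)] = m_lin
            total_daily = total_daily + m_lin
        total_daily = np.minimum(1.0, total_daily)
        td = doubling_time(temp, host)
        out[schema.mortality_col("daily", host_key)] = total_daily
        out[schema.mortality_col("generation", host_key)] = generation_mortality(
            total_daily, td, convention=mu_convention)
        out[f"doubling_time_{host_key}_d"] = td
    return out
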