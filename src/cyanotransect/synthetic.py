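"""Seeded synthetic transects, CTD profiles and polony counts with known truth.

The generator emulates the structure of spring/early-summer surveys between the
North Pacific Subtropical and Subpolar gyres: smooth latitudinal temperature,
salinity and chlorophyll gradients; a logistic *Prochlorococcus* decline near
its thermal limit; a transition-zone *Synechococcus* peak; a Gaussian-in-
temperature cyanophage hotspot near 15–16 °C superimposed on a temperature x
chlorophyll regression surface; and Poisson polony-count sampling with known
detection efficiencies.  Generation is static/statistical — there is no
host–virus population dynamics here, only parametric surfaces plus noise —
so every downstream stage can be tested against exact ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import schema

__all__ = [
    "TransectScenario",
    "GroundTruth",
    "generate_transect",
    "simulate_polony_counts",
    "generate_ctd_profile",
    "simulate_regression_dataset",
    "default_temperature",
    "default_salinity",
    "default_chlorophyll",
]


# ---------------------------------------------------------------------------
# default latitudinal profiles (one representative 158° W spring section)

def default_temperature(lat: np.ndarray) -> np.ndarray:
    """Sea-surface temperature (°C), strictly decreasing with latitude."""
    lat = np.asarray(lat, dtype=float)
    return 24.0 - 0.52 * (lat - 22.0)


def default_salinity(lat: np.ndarray) -> np.ndarray:
    """Surface salinity (PSU): saline gyre water, logistic drop across the
    transition zone toward fresher subpolar water."""
    lat = np.asarray(lat, dtype=float)
    return 35.1 - 2.6 * expit((lat - 38.0) / 1.5)


def default_chlorophyll(lat: np.ndarray) -> np.ndarray:
    """Surface chlorophyll (mg m^-3): oligotrophic south, rising logistically
    across the chlorophyll front into productive subpolar water."""
    lat = np.asarray(lat, dtype=float)
    return 0.07 + 0.5 * expit((lat - 39.0) / 1.2)


@dataclass(frozen=True)
class TransectScenario:
    """Configuration of one synthetic multi-cruise survey.

    All constants are configuration, not assertions: defaults are set to the
    ranges reported for the study system (subtropical cyanophage mean near
    5.7e5 ml^-1, 3–10x hotspot enrichment, Prochlorococcus 1.5–3e5 ml^-1,
    hotspot near 15–16 °C) so that fixtures are realistic.
    """

    seed: int = 0
    n_samples: int = 40                      # per cruise
    cruise_ids: tuple[str, ...] = ("KM15", "KOK16", "MGL17")
    latitude_range: tuple[float, float] = (22.0, 46.0)
    temperature_profile: Callable[[np.ndarray], np.ndarray] = default_temperature
    salinity_profile: Callable[[np.ndarray], np.ndarray] = default_salinity
    chlorophyll_profile: Callable[[np.ndarray], np.ndarray] = default_chlorophyll

    # hosts: (thermal midpoint °C, logistic width °C, max abundance ml^-1)
    pro_thermal_midpoint_c: float = 12.0
    pro_thermal_width_c: float = 1.0
    pro_max_ml: float = 2.2e5
    syn_base_ml: float = 5e3
    syn_peak_ml: float = 8e4
    syn_peak_center_c: float = 14.0
    syn_peak_width_c: float = 3.0
    het_base_ml: float = 5e5
    # virus-driven suppression of Prochlorococcus inside the hotspot band
    # (per-cruise override mirrors the inter-annual contrast: one cruise with a
    # deep, virus-driven Prochlorococcus collapse, two with milder dips)
    pro_suppression: float = 0.5

    # Gaussian-in-temperature cyanophage hotspot
    hotspot_center_c: float = 15.5
    hotspot_width_c: float = 1.5             # Gaussian sigma
    hotspot_amplitude: float = 1.5e6         # viruses ml^-1 at the peak

    # log10 abundance = k0 + k1*T + k2*Chl + k3*T*Chl  (total cyanophages)
    regression_truth: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {"total": (4.0, 0.08, -2.0, 0.1)}
    )

    # multiplicative noise (sd of log10) and observation noise
    noise_sd: float = 0.15
    chl_noise_sd: float = 0.08
    host_noise_sd: float = 0.10
    infection_noise_sd: float = 0.10
    # shared lognormal "biomass anomaly" between hosts and phage: in the flat
    # subtropical field it produces the positive phage-host co-variation
    # expected when viruses are host-limited.  Capped by noise_sd/host_noise_sd.
    biomass_noise_sd: float = 0.09

    # per-cruise multiplicative scale on phage abundances (inter-annual
    # variability; 1.0 when a cruise is not listed)
    cruise_scale: Mapping[str, float] = field(
        default_factory=lambda: {"MGL17": 1.25, "KOK16": 0.95}
    )
    # per-cruise additive temperature offset (°C): the hotspot stays anchored
    # in temperature while shifting in latitude between cruises
    cruise_temp_offset: Mapping[str, float] = field(
        default_factory=lambda: {"KM15": 0.3, "MGL17": -0.4}
    )
    cruise_pro_suppression: Mapping[str, float] = field(
        default_factory=lambda: {"MGL17": 0.9}
    )

    # infection link: I = I_max * (A/A_half)^h / (1 + (A/A_half)^h)
    infection_max: float = 0.12
    infection_half_sat: float = 1.3e6
    infection_hill: float = 3.5

    detection_efficiency: Mapping[str, float] = field(
        default_factory=lambda: {"t7a": 0.80, "t7b": 0.85, "t4": 0.75, "tim5": 0.80}
    )

    daylight_hours: float = 12.0

    def __post_init__(self) -> None:
        lo, hi = self.latitude_range
        if not hi > lo:
            raise ValueError("latitude_range must satisfy lo < hi")
        if self.hotspot_amplitude < 0:
            raise ValueError("hotspot_amplitude must be >= 0")
        for lin, eff in self.detection_efficiency.items():
            if not 0 < eff <= 1:
                raise ValueError(f"detection efficiency for {lin} must be in (0, 1]")
        lats = np.linspace(lo, hi, 201)
        temps = np.asarray(self.temperature_profile(lats), dtype=float)
        if not np.all(np.diff(temps) < 0):
            raise ValueError(
                "temperature_profile must be strictly decreasing with latitude "
                "(temperature<->latitude mapping must be invertible)"
            )

    def replace(self, **kw) -> "TransectScenario":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Per-sample truth underlying one generated survey.

    ``table`` is indexed like the sample table and holds the noise-free phage
    abundances (total and per lineage) and infected fractions.
    """

    table: pd.DataFrame
    hotspot_center_c: float
    hotspot_width_c: float
    hotspot_amplitude: float
    #: inflection-based temperature band of the injected bump, center ± sqrt(3)·sigma
    hotspot_range_c: tuple[float, float]
    regression_truth: dict[str, tuple[float, float, float, float]]
    infection_link: dict[str, float]


def _lineage_weights(temp: np.ndarray, center: float, width: float) -> dict[str, np.ndarray]:
    """Cyanophage community composition as a function of temperature.

    T4-like dominate the warm gyre; T7-like clade B surge inside the hotspot
    band; T7-like clade A rise at its northern edge; TIM5-like remain a minor,
    cold-water group.  Weights are normalized to sum to 1 per sample.
    """
    bump = np.exp(-((temp - center) ** 2) / (2 * width**2))
    raw = {
        "t4": 0.60 - 0.25 * bump,
        "t7b": 0.28 + 0.40 * bump,
        "t7a": 0.06 + 0.10 * np.exp(-((temp - (center - 1.5)) ** 2) / (2 * 1.0**2)),
        "tim5": 0.06 + 0.06 * expit((14.0 - temp) / 1.0),
    }
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def infection_link(abundance, i_max: float, half_sat: float, hill: float):
    """Saturating (Hill) link from true phage abundance to infected fraction.

    A steep link (exponent > 1) encodes the positive feedback between infection
    and virus production that concentrates infection in the hotspot; it is a
    fixture choice, not an inference from data.
    """
    a = np.asarray(abundance, dtype=float)
    x = np.power(np.clip(a, 0.0, None) / half_sat, hill)
    return np.clip(i_max * x / (1.0 + x), 0.0, 1.0)


def generate_transect(scenario: TransectScenario) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one seeded multi-cruise surface transect and its ground truth.

    Returns the canonical sample table (one row per observation, ordered by
    cruise then latitude) and a :class:`GroundTruth` record.  With
    ``noise_sd=0`` and ``hotspot_amplitude=0`` the observed total phage
    abundance equals the regression-truth surface exactly.
    """
    if scenario.n_samples < 10:
        raise ValueError("need n_samples >= 10 per cruise")
    rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.latitude_range
    frames = []
    truth_frames = []
    k0, k1, k2, k3 = scenario.regression_truth["total"]

    for cruise in scenario.cruise_ids:
        n = scenario.n_samples
        # evenly spaced stations with jitter, sorted south -> north
        base = np.linspace(lo, hi, n)
        jitter = rng.uniform(-0.5, 0.5, n) * (hi - lo) / (2 * n)
        lats = np.sort(np.clip(base + jitter, lo, hi))
        t_offset = dict(scenario.cruise_temp_offset).get(cruise, 0.0)
        temp = np.asarray(scenario.temperature_profile(lats), dtype=float) + t_offset
        sal = np.asarray(scenario.salinity_profile(lats), dtype=float)
        chl_true = np.asarray(scenario.chlorophyll_profile(lats), dtype=float)
        chl = chl_true * 10 ** rng.normal(0.0, scenario.chl_noise_sd, n)

        # shared biomass anomaly, capped so total noise budgets are honoured
        shared_phage = min(scenario.biomass_noise_sd, scenario.noise_sd)
        shared_host = min(scenario.biomass_noise_sd, scenario.host_noise_sd)
        anomaly = rng.standard_normal(n)

        # hosts
        pro_logistic = expit((temp - scenario.pro_thermal_midpoint_c) / scenario.pro_thermal_width_c)
        bump_norm = np.exp(
            -((temp - scenario.hotspot_center_c) ** 2) / (2 * scenario.hotspot_width_c**2)
        )
        suppression = dict(scenario.cruise_pro_suppression).get(cruise, scenario.pro_suppression)
        pro_true = scenario.pro_max_ml * pro_logistic * (1 - suppression * bump_norm)
        syn_true = scenario.syn_base_ml + scenario.syn_peak_ml * np.exp(
            -((temp - scenario.syn_peak_center_c) ** 2) / (2 * scenario.syn_peak_width_c**2)
        )
        het_true = scenario.het_base_ml * (1 + 1.5 * expit((chl_true - 0.2) / 0.1))

        host_indep = np.sqrt(max(scenario.host_noise_sd**2 - shared_host**2, 0.0))
        pro = pro_true * 10 ** (shared_host * anomaly + rng.normal(0.0, host_indep, n))
        syn = syn_true * 10 ** (shared_host * anomaly + rng.normal(0.0, host_indep, n))
        het = het_true * 10 ** rng.normal(0.0, scenario.host_noise_sd, n)

        # cyanophages: regression surface (on the *observed* chlorophyll, so the
        # measured covariate is the one the abundances respond to) + hotspot bump
        scale = dict(scenario.cruise_scale).get(cruise, 1.0)
        mean_total = 10 ** (k0 + k1 * temp + k2 * chl + k3 * temp * chl)
        total_true = scale * (mean_total + scenario.hotspot_amplitude * bump_norm)
        phage_indep = np.sqrt(max(scenario.noise_sd**2 - shared_phage**2, 0.0))
        if scenario.noise_sd == 0:
            total_obs = total_true.copy()
        else:
            total_obs = total_true * 10 ** (
                shared_phage * anomaly + rng.normal(0.0, phage_indep, n))

        weights = _lineage_weights(temp, scenario.hotspot_center_c, scenario.hotspot_width_c)

        # infection: saturating link on the true total abundance
        i_total = infection_link(
            total_true, scenario.infection_max, scenario.infection_half_sat, scenario.infection_hill
        )

        df = pd.DataFrame(
            {
                schema.CRUISE: cruise,
                schema.LAT: lats,
                schema.LON: -158.0,
                schema.TEMP: temp,
                schema.SAL: sal,
                schema.CHL: chl,
                schema.PRO: pro,
                schema.SYN: syn,
                schema.HET: het,
                schema.PHAGE_TOTAL: total_obs,
                schema.DAYLIGHT: scenario.daylight_hours,
            }
        )
        tdf = pd.DataFrame(
            {
                schema.CRUISE: cruise,
                schema.LAT: lats,
                schema.TEMP: temp,
                "true_" + schema.PHAGE_TOTAL: total_true,
                "true_" + schema.PRO: pro_true,
                "true_" + schema.SYN: syn_true,
            }
        )
        for lin in schema.LINEAGES:
            lin_true = total_true * weights[lin]
            df[schema.phage_col(lin)] = lin_true * 10 ** rng.normal(0.0, scenario.noise_sd, n)
            tdf["true_" + schema.phage_col(lin)] = lin_true
        for host in schema.HOSTS:
            lins = schema.HOST_LINEAGES[host]
            w_tot = sum(weights[l] for l in lins)
            host_total_obs = np.zeros(n)
            for lin in lins:
                i_lin = i_total * weights[lin] / w_tot
                obs = np.clip(
                    i_lin * 10 ** rng.normal(0.0, scenario.infection_noise_sd, n), 0.0, 1.0
                )
                df[schema.infected_col(host, lin)] = obs
                host_total_obs += obs
                tdf["true_" + schema.infected_col(host, lin)] = i_lin
            df[schema.infected_col(host)] = np.clip(host_total_obs, 0.0, 1.0)
            tdf["true_" + schema.infected_col(host)] = i_total
        # leucine incorporation tracks the trophic gradient
        leu_true = 15.0 + 60.0 * chl_true / (chl_true + 0.3)
        df[schema.LEUCINE] = leu_true * 10 ** rng.normal(0.0, 0.05, n)
        frames.append(df)
        truth_frames.append(tdf)

    samples = pd.concat(frames, ignore_index=True)
    truth_table = pd.concat(truth_frames, ignore_index=True)
    half = np.sqrt(3.0) * scenario.hotspot_width_c
    truth = GroundTruth(
        table=truth_table,
        hotspot_center_c=scenario.hotspot_center_c,
        hotspot_width_c=scenario.hotspot_width_c,
        hotspot_amplitude=scenario.hotspot_amplitude,
        hotspot_range_c=(scenario.hotspot_center_c - half, scenario.hotspot_center_c + half),
        regression_truth={k: tuple(v) for k, v in scenario.regression_truth.items()},
        infection_link={
            "i_max": scenario.infection_max,
            "half_sat": scenario.infection_half_sat,
            "hill": scenario.infection_hill,
        },
    )
    return samples, truth


def simulate_polony_counts(
    true_conc: float,
    volume_ml: float,
    efficiency: float,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 1,
) -> np.ndarray:
    """Poisson polony counts for a reaction observing ``true_conc`` viruses ml^-1.

    Counts ~ Poisson(conc x volume x efficiency): binomial thinning by the
    detection efficiency is absorbed into the Poisson rate.
    """
    if volume_ml <= 0:
        raise ValueError("volume must be > 0")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    if true_conc < 0:
        raise ValueError("concentration must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = true_conc * volume_ml * efficiency
    return rng.poisson(lam, size=n_replicates)


def generate_ctd_profile(
    mld_true: float,
    surface_density: float = 1024.0,
    seed: int | np.random.Generator = 0,
    depth_step: float = 2.0,
    max_depth: float = 200.0,
    noise_sd: float = 0.003,
    pycnocline_slope: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic CTD (depth m, potential density kg m^-3) pairs.

    Density is constant (± noise < 0.01 kg m^-3) above ``mld_true`` and then
    increases at ``pycnocline_slope`` kg m^-3 per metre, so the first depth
    exceeding surface density + 0.1 kg m^-3 lies within one depth bin of truth.
    """
    if mld_true <= 0:
        raise ValueError("mld_true must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depths = np.arange(0.0, max_depth + depth_step / 2, depth_step)
    density = surface_density + np.clip(depths - mld_true, 0.0, None) * pycnocline_slope
    density = density + rng.normal(0.0, noise_sd, depths.size)
    density[0] = surface_density
    return depths, density


def simulate_regression_dataset(
    coeffs: tuple[float, float, float, float],
    n: int,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    temp_range: tuple[float, float] = (9.0, 25.0),
) -> pd.DataFrame:
    """Samples drawn exactly from the log-linear T x Chl surface plus noise.

    Chlorophyll co-varies with temperature as on a real section (cold water is
    greener) with independent lognormal scatter, so the design is realistic but
    full rank.  Used by parameter-recovery and interval-coverage checks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k0, k1, k2, k3 = coeffs
    temp = rng.uniform(*temp_range, n)
    chl = (0.07 + 0.5 * expit((16.0 - temp) / 1.2)) * 10 ** rng.normal(0.0, 0.2, n)
    log_abund = k0 + k1 * temp + k2 * chl + k3 * temp * chl + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(
        {schema.TEMP: temp, schema.CHL: chl, schema.PHAGE_TOTAL: 10**log_abund}
    )
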