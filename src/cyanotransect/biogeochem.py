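"""Viral-shunt carbon, nitrogen and phosphorus budgets.

Lysis of picocyanobacteria releases the cell's carbon minus the carbon locked
into progeny virions:

    L_vir = P * M_Pro * (C_Pro - C_vir * B) + S * M_Syn * (C_Syn - C_vir * B)

computed per cyanophage lineage (each with its own virion carbon and burst
size) and summed.  Carbon converts to N and P through host elemental ratios,
integrates over regime area x mixed-layer depth, and is compared with the
bacterial carbon demand derived from leucine-incorporation bacterial
production and an assumed growth efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import schema
from .mortality import DEFAULT_HOSTS, DEFAULT_LINEAGES, HostParams, LineageParams

__all__ = [
    "LysateFlux",
    "lysate_flux",
    "fg_per_ml_to_umol_per_l",
    "umol_per_l_to_fg_per_ml",
    "regime_volume_l",
    "stoichiometric_convert",
    "regime_integrate",
    "bacterial_production",
    "carbon_demand_fraction",
    "dom_comparison",
    "regime_budget",
    "DOM_REFERENCE_UMOL",
    "CARBON_MOLAR_MASS",
]

CARBON_MOLAR_MASS = 12.011  # g mol^-1

#: previously reported dissolved organic-matter production, µmol l^-1 d^-1
DOM_REFERENCE_UMOL = {"c": 0.07, "n": 33.6e-3, "p": 1.8e-3}


def fg_per_ml_to_umol_per_l(flux_fg_ml: float, molar_mass: float = CARBON_MOLAR_MASS) -> float:
    """fg element ml^-1 -> µmol element l^-1 (exact unit chain)."""
    return flux_fg_ml * 1e-6 / molar_mass


def umol_per_l_to_fg_per_ml(flux_umol_l: float, molar_mass: float = CARBON_MOLAR_MASS) -> float:
    return flux_umol_l * molar_mass * 1e6


def regime_volume_l(area_km2: float, mld_m: float) -> float:
    """Mixed-layer volume in litres: area x 10^6 m^2 km^-2 x MLD x 10^3 l m^-3."""
    if area_km2 < 0 or mld_m < 0:
        raise ValueError("area and mixed-layer depth must be >= 0")
    return area_km2 * 1e6 * mld_m * 1e3


@dataclass
class LysateFlux:
    """Virus-released organic carbon flux with per-lineage/per-host breakdown."""

    total_fg_ml_d: float
    per_lineage_fg_ml_d: dict[str, float] = field(default_factory=dict)
    per_host_fg_ml_d: dict[str, float] = field(default_factory=dict)

    @property
    def umol_c_l_d(self) -> float:
        return fg_per_ml_to_umol_per_l(self.total_fg_ml_d)


def lysate_flux(
    pro_ml: float,
    syn_ml: float,
    m_pro_by_lineage: Mapping[str, float],
    m_syn_by_lineage: Mapping[str, float],
    hosts: Mapping[str, HostParams] = DEFAULT_HOSTS,
    lineages: Mapping[str, LineageParams] = DEFAULT_LINEAGES,
) -> LysateFlux:
    """Daily virus-mediated organic carbon release (fg C ml^-1 d^-1).

    Mortality is attributed per lineage (keys of the mortality mappings), each
    lineage removing its virion-carbon payload ``C_vir x B`` from the lysed
    cell quota.  A payload at or above the cell quota is unphysical for these
    systems (a single virion is <0.5% of cellular carbon) and raises.
    """
    if pro_ml < 0 or syn_ml < 0:
        raise ValueError("host abundances must be >= 0")
    per_lineage: dict[str, float] = {}
    per_host = {"pro": 0.0, "syn": 0.0}
    for host_key, abundance, m_by_lin in (
        ("pro", pro_ml, m_pro_by_lineage),
        ("syn", syn_ml, m_syn_by_lineage),
    ):
        quota = hosts[host_key].carbon_quota_fg
        for lin, m in m_by_lin.items():
            if not 0 <= m <= 1:
                raise ValueError(f"mortality for {lin} must be in [0, 1]")
            payload = lineages[lin].virion_carbon_fg * lineages[lin].burst_size
            if payload >= quota:
                raise ValueError(
                    f"virion carbon payload {payload} fg >= {host_key} quota {quota} fg; "
                    "a single virus particle should be <0.5% of cellular carbon"
                )
            flux = abundance * m * (quota - payload)
            per_lineage[lin] = per_lineage.get(lin, 0.0) + flux
            per_host[host_key] += flux
    total = sum(per_host.values())
    return LysateFlux(total, per_lineage, per_host)


def stoichiometric_convert(
    carbon_flux_umol: float, host: HostParams
) -> tuple[float, float]:
    """Convert a molar carbon flux to (N, P) fluxes via host C:P and N:P ratios."""
    if host.c_to_p <= 0 or host.n_to_p <= 0:
        raise ValueError("missing or invalid elemental ratios")
    p_flux = carbon_flux_umol / host.c_to_p
    n_flux = p_flux * host.n_to_p
    return n_flux, p_flux


def regime_integrate(
    flux: float,
    area_km2: float,
    mld_m: float,
    units: str = "umol_c_per_l_per_d",
) -> float:
    """Integrate a volumetric carbon flux over a regime: returns g C d^-1.

    The flux must be tagged with its units; anything but µmol C l^-1 d^-1 is
    rejected rather than silently converted.
    """
    if units != "umol_c_per_l_per_d":
        raise ValueError(f"flux units must be 'umol_c_per_l_per_d', got {units!r}")
    if area_km2 <= 0 or mld_m <= 0:
        return 0.0 if area_km2 == 0 or mld_m == 0 else _raise_neg()
    return flux * regime_volume_l(area_km2, mld_m) * 1e-6 * CARBON_MOLAR_MASS


def _raise_neg():
    raise ValueError("area and mixed-layer depth must be positive")


def bacterial_production(
    leucine_pmol_l_h: float,
    leucine_molar_mass: float = 131.2,
    leucine_protein_fraction: float = 0.073,
    carbon_per_protein: float = 0.86,
) -> float:
    """Bacterial production (µmol C l^-1 d^-1) from leucine incorporation.

    Chain: pmol Leu -> g Leu (x131.2 g mol^-1) -> g protein (/0.073) ->
    g C (x0.86) -> per day (x24) -> µmol C (/12.011).  All constants are
    exposed for alternative conversion factors.
    """
    if leucine_pmol_l_h < 0:
        raise ValueError("leucine incorporation rate must be >= 0")
    ug_c_l_h = (leucine_pmol_l_h * 1e-6 * leucine_molar_mass
                / leucine_protein_fraction * carbon_per_protein)
    return ug_c_l_h * 24.0 / CARBON_MOLAR_MASS


def carbon_demand_fraction(
    lysate_c_umol: float,
    bacterial_production_umol: float,
    growth_efficiency: float = 0.15,
) -> float:
    """Fraction of the bacterial carbon demand sustained by viral lysate.

    BCD = BP / growth efficiency.  Values above 1 are possible (lysate exceeds
    demand) and flagged with a warning rather than clipped.
    """
    if not 0 < growth_efficiency <= 1:
        raise ValueError("growth efficiency must be in (0, 1]")
    if bacterial_production_umol <= 0:
        warnings.warn("zero bacterial production; demand fraction undefined", stacklevel=2)
        return float("nan")
    frac = lysate_c_umol / (bacterial_production_umol / growth_efficiency)
    if frac > 1:
        warnings.warn("lysate exceeds the bacterial carbon demand", stacklevel=2)
    return frac


def dom_comparison(
    fluxes_umol: Mapping[str, float],
    references_umol: Mapping[str, float] = DOM_REFERENCE_UMOL,
) -> dict[str, float]:
    """Ratio of computed lysate fluxes to reported DOM production rates.

    Both mappings are keyed by element ("c", "n", "p") in µmol l^-1 d^-1.
    """
    out = {}
    for elem, value in fluxes_umol.items():
        ref = references_umol.get(elem)
        if ref is None or ref == 0:
            raise ValueError(f"missing or zero reference rate for element {elem!r}")
        out[elem] = value / ref
    return out


def regime_budget(
    df: pd.DataFrame,
    areas_km2: Mapping[str, float],
    mld_m: Mapping[str, float],
    hosts: Mapping[str, HostParams] = DEFAULT_HOSTS,
    lineages: Mapping[str, LineageParams] = DEFAULT_LINEAGES,
    growth_efficiency: float = 0.15,
) -> pd.DataFrame:
    """Per-regime viral-shunt budget from a mortality-annotated transect table.

    For each regime: the mean per-sample lysate flux, its N/P conversion, the
    regime-integrated carbon release (area x mixed-layer depth), leucine-based
    bacterial production, and the fraction of bacterial carbon demand the
    lysate could sustain.
    """
    rows = []
    for regime, g in df.groupby(schema.REGIME):
        if regime not in areas_km2:
            continue
        fluxes = []
        n_umol = p_umol = 0.0
        for _, row in g.iterrows():
            m_pro = {}
            m_syn = {}
            for lin in schema.LINEAGES:
                c_pro = schema.mortality_col("daily", "pro", lin)
                c_syn = schema.mortality_col("daily", "syn", lin)
                if c_pro in row.index:
                    m_pro[lin] = float(row[c_pro])
                if c_syn in row.index:
                    m_syn[lin] = float(row[c_syn])
            lf = lysate_flux(row[schema.PRO], row[schema.SYN], m_pro, m_syn,
                             hosts=hosts, lineages=lineages)
            fluxes.append(lf)
        mean_fg = float(np.mean([f.total_fg_ml_d for f in fluxes]))
        mean_umol = fg_per_ml_to_umol_per_l(mean_fg)
        # N/P conversion uses each host's own stoichiometry
        pro_umol = fg_per_ml_to_umol_per_l(float(np.mean([f.per_host_fg_ml_d["pro"] for f in fluxes])))
        syn_umol = fg_per_ml_to_umol_per_l(float(np.mean([f.per_host_fg_ml_d["syn"] for f in fluxes])))
        n_pro, p_pro = stoichiometric_convert(pro_umol, hosts["pro"])
        n_syn, p_syn = stoichiometric_convert(syn_umol, hosts["syn"])
        n_umol = n_pro + n_syn
        p_umol = p_pro + p_syn
        area = areas_km2[regime]
        mld = mld_m[regime]
        total_g_d = regime_integrate(mean_umol, area, mld)
        bp = bacterial_production(float(g[schema.LEUCINE].mean())) \
            if schema.LEUCINE in g.columns else float("nan")
        frac = carbon_demand_fraction(mean_umol, bp, growth_efficiency) \
            if np.isfinite(bp) and bp > 0 else float("nan")
        rows.append({
            schema.REGIME: regime,
            "area_km2": area,
            "mean_mld_m": mld,
            "volume_l": regime_volume_l(area, mld),
            "lysate_c_umol_l_d": mean_umol,
            "lysate_n_umol_l_d": n_umol,
            "lysate_p_umol_l_d": p_umol,
            "total_lysate_c_g_d": total_g_d,
            "bacterial_production_umol_l_d": bp,
            "bcd_umol_l_d": bp / growth_efficiency if np.isfinite(bp) else float("nan"),
            "fraction_bcd_sustained": frac,
            "n_samples": len(g),
        })
    return pd.DataFrame(rows)
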