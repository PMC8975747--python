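"""Canonical column schema for the transect table.

Every module reads and writes the same plain-CSV dialect; the names below are
the single source of truth.  One row is one surface-water observation.
"""

from __future__ import annotations

SCHEMA_VERSION = "1"

CRUISE = "cruise_id"
LAT = "latitude"
LON = "longitude"
TEMP = "temperature_c"
SAL = "salinity_psu"
CHL = "chlorophyll_mg_m3"
PRO = "prochlorococcus_ml"
SYN = "synechococcus_ml"
HET = "heterotrophic_bacteria_ml"
LEUCINE = "leucine_pmol_l_h"
DAYLIGHT = "daylight_h"

#: cyanophage lineages assayed by the polony method
LINEAGES = ("t7a", "t7b", "t4", "tim5")

#: hosts resolved by the single-cell infection assay
HOSTS = ("pro", "syn")

#: lineages considered to infect each host (TIM5-like are Synechococcus-specific)
HOST_LINEAGES = {"pro": ("t7a", "t7b", "t4"), "syn": ("t7a", "t7b", "t4", "tim5")}

PHAGE_TOTAL = "cyanophage_total_ml"


def phage_col(lineage: str) -> str:
    """Column holding the free-phage abundance of one lineage (viruses ml^-1)."""
    return f"phage_{lineage}_ml"


def infected_col(host: str, lineage: str | None = None) -> str:
    """Column holding an infected fraction (dimensionless, in [0, 1]).

    With ``lineage=None`` the column is the host's total infected fraction.
    """
    if lineage is None:
        return f"infected_{host}_frac"
    return f"infected_{host}_{lineage}_frac"


# columns appended by downstream stages
REGIME = "regime"
NORTH_OF_FRONT = "north_of_front"
SCALED = "phage_scaled"
CENTERED = "phage_centered"


def mortality_col(kind: str, host: str, lineage: str | None = None) -> str:
    """Mortality columns: ``kind`` is 'daily' or 'generation'."""
    base = f"m_{kind}_{host}"
    return base if lineage is None else f"{base}_{lineage}"


REQUIRED_INPUT = (CRUISE, LAT, TEMP, SAL, CHL, PRO, SYN)
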