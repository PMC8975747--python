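"""Quantification of polony assays.

Raw polony counts (single-molecule PCR colonies) are converted to free
cyanophage concentrations or infected-cell fractions, with detection-efficiency
corrections, a co-sorted free-phage correction, early/late infection-stage
bounds, and bootstrap 95% confidence intervals.

Detection efficiencies are lineage-specific, empirically measured quantities;
the defaults here are 1.0 (no correction) and users supply measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolonyAssay",
    "QuantResult",
    "phage_concentration",
    "infected_fraction",
    "infection_bounds",
    "infected_abundance",
    "bootstrap_ci",
    "efficiency_sampler_from",
    "free_phage_correction_from_concentration",
]


@dataclass
class PolonyAssay:
    """One polony reaction set (technical replicates of a single sample).

    Free-phage mode sets ``input_volume_ml``; infected-cell mode sets
    ``cells_sorted``.  ``efficiency`` is the best-estimate detection
    efficiency; ``efficiency_early``/``efficiency_late`` bracket it (detection
    is lowest early in infection and highest late).
    """

    lineage: str
    replicate_counts: np.ndarray
    input_volume_ml: float | None = None
    cells_sorted: float | None = None
    efficiency: float = 1.0
    efficiency_early: float | None = None
    efficiency_late: float | None = None
    free_phage_correction: float = 0.0
    #: optional repeated efficiency measurements, resampled by the bootstrap
    efficiency_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.replicate_counts = np.asarray(self.replicate_counts, dtype=float)
        if np.any(self.replicate_counts < 0):
            raise ValueError("replicate counts must be non-negative")
        if self.replicate_counts.size < 2:
            warnings.warn("fewer than 2 technical replicates; CI undefined", stacklevel=2)
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        early = self.efficiency if self.efficiency_early is None else self.efficiency_early
        late = self.efficiency if self.efficiency_late is None else self.efficiency_late
        if not 0 < early <= self.efficiency <= late <= 1:
            raise ValueError("require 0 < efficiency_early <= efficiency <= efficiency_late <= 1")
        self.efficiency_early = early
        self.efficiency_late = late


@dataclass
class QuantResult:
    """Point estimate with bootstrap CI and (infected-cell mode) stage bounds."""

    point_estimate: float
    ci95: tuple[float, float]
    n_replicates: int
    bounds: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)


def efficiency_sampler_from(values, beta_concentration: float = 50.0):
    """Build an efficiency sampler for the bootstrap.

    A set of repeated measurements is resampled with replacement; a single
    point value is jittered with a Beta distribution matching that mean (the
    choice of sampler is a modelling decision, exposed here).
    """
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("efficiencies must be in (0, 1]")
    if arr.size == 1:
        eff = float(arr[0])
        if eff == 1.0:
            return lambda rng, size: np.full(size, 1.0)
        a = eff * beta_concentration
        b = (1 - eff) * beta_concentration
        return lambda rng, size: rng.beta(a, b, size)
    return lambda rng, size: rng.choice(arr, size=size, replace=True)


def free_phage_correction_from_concentration(
    free_phage_ml: float, cells_sorted: float, carryover_per_cell_ml: float
) -> float:
    """Expected co-sorted free-phage polonies per reaction.

    Each sorted cell carries over a small droplet volume; the correction is the
    measured free-phage concentration times the total carried-over volume.
    """
    if min(free_phage_ml, cells_sorted, carryover_per_cell_ml) < 0:
        raise ValueError("inputs must be non-negative")
    return free_phage_ml * cells_sorted * carryover_per_cell_ml


def bootstrap_ci(
    replicate_counts,
    normalizer: float,
    efficiency_sampler=None,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    resample_counts: str = "poisson",
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for mean(counts) / (normalizer x efficiency).

    ``resample_counts`` selects how count variability is resampled:

    - ``"poisson"`` (default): parametric — replicate counts are redrawn from
      Poisson(mean count), appropriate for single-molecule counting where few
      technical replicates are available;
    - ``"replicates"``: nonparametric resampling of the observed replicates;
    - ``"none"``: counts held fixed (efficiency uncertainty only).

    Efficiency draws come from ``efficiency_sampler(rng, size)``; ``None``
    means a fixed efficiency of 1 folded into ``normalizer``.
    """
    counts = np.asarray(replicate_counts, dtype=float)
    if counts.size < 1:
        raise ValueError("need at least one replicate")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if normalizer <= 0:
        raise ValueError("normalizer must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = counts.size
    if resample_counts == "poisson":
        means = rng.poisson(counts.mean(), size=(n_boot, k)).mean(axis=1)
    elif resample_counts == "replicates":
        idx = rng.integers(0, k, size=(n_boot, k))
        means = counts[idx].mean(axis=1)
    elif resample_counts == "none":
        means = np.full(n_boot, counts.mean())
    else:
        raise ValueError(f"unknown resample_counts mode: {resample_counts!r}")
    eff = 1.0 if efficiency_sampler is None else efficiency_sampler(rng, n_boot)
    stats = means / (normalizer * eff)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _ci_for(assay: PolonyAssay, normalizer: float, n_boot: int, seed, resample_counts: str,
            correction: float = 0.0) -> tuple[tuple[float, float], list[str]]:
    flags: list[str] = []
    counts = assay.replicate_counts
    if counts.size < 2 and resample_counts == "replicates":
        flags.append("single_replicate_ci_undefined")
        point = counts.mean() / normalizer
        return (point, point), flags
    sampler = None
    if assay.efficiency_values is not None:
        sampler = efficiency_sampler_from(assay.efficiency_values)
        norm = normalizer / assay.efficiency  # efficiency supplied by sampler
    else:
        norm = normalizer
    if correction:
        # shift-then-clip: the correction is subtracted from each bootstrap mean
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        k = counts.size
        if resample_counts == "poisson":
            means = rng.poisson(counts.mean(), size=(n_boot, k)).mean(axis=1)
        elif resample_counts == "replicates":
            idx = rng.integers(0, k, size=(n_boot, k))
            means = counts[idx].mean(axis=1)
        else:
            means = np.full(n_boot, counts.mean())
        eff = 1.0 if sampler is None else sampler(rng, n_boot)
        stats = np.clip(means - correction, 0.0, None) / (norm * eff)
        lo, hi = np.quantile(stats, [0.025, 0.975])
        ci = (float(lo), float(hi))
    else:
        ci = bootstrap_ci(counts, norm, sampler, n_boot=n_boot, seed=seed,
                          resample_counts=resample_counts)
    if ci[0] == ci[1]:
        flags.append("zero_width_ci")
    return ci, flags


def phage_concentration(
    assay: PolonyAssay,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    resample_counts: str = "poisson",
) -> QuantResult:
    """Free-cyanophage concentration (viruses ml^-1) from a free-phage assay.

    point = mean(counts) / (volume x efficiency).
    """
    if assay.input_volume_ml is None:
        raise ValueError("free-phage mode requires input_volume_ml")
    if assay.input_volume_ml <= 0:
        raise ValueError("input volume must be > 0")
    norm = assay.input_volume_ml * assay.efficiency
    point = float(assay.replicate_counts.mean() / norm)
    ci, flags = _ci_for(assay, norm, n_boot, seed, resample_counts)
    lo = min(ci[0], point)
    hi = max(ci[1], point)
    return QuantResult(point, (lo, hi), assay.replicate_counts.size, flags=flags)


def infection_bounds(assay: PolonyAssay) -> tuple[float, float]:
    """(lower, upper) infected-fraction bounds from the stage-dependent efficiency.

    All-late-stage infections (maximal detection) give the lower bound;
    all-early-stage (minimal detection) give the upper bound.
    """
    if assay.cells_sorted is None:
        raise ValueError("infected-cell mode requires cells_sorted")
    corrected = max(0.0, assay.replicate_counts.mean() - assay.free_phage_correction)
    upper = min(1.0, corrected / (assay.cells_sorted * assay.efficiency_early))
    lower = min(1.0, corrected / (assay.cells_sorted * assay.efficiency_late))
    return lower, upper


def infected_fraction(
    assay: PolonyAssay,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    resample_counts: str = "poisson",
) -> QuantResult:
    """Infected-cell fraction from a sorted-cell assay.

    point = max(0, mean(counts) - free_phage_correction) / (cells x efficiency),
    clipped to [0, 1]; stage bounds computed via :func:`infection_bounds`.
    """
    if assay.cells_sorted is None:
        raise ValueError("infected-cell mode requires cells_sorted")
    if assay.cells_sorted <= 0:
        raise ValueError("cells_sorted must be > 0")
    raw = assay.replicate_counts.mean() - assay.free_phage_correction
    flags: list[str] = []
    if raw <= 0 and assay.free_phage_correction > 0:
        flags.append("correction_exceeds_counts")
        raw = 0.0
    raw = max(raw, 0.0)
    norm = assay.cells_sorted * assay.efficiency
    point = float(min(1.0, raw / norm))
    ci, ci_flags = _ci_for(assay, norm, n_boot, seed, resample_counts,
                           correction=assay.free_phage_correction)
    flags += ci_flags
    lo = float(min(max(ci[0], 0.0), point))
    hi = float(min(max(ci[1], point), 1.0))
    bounds = infection_bounds(assay)
    bounds = (min(bounds[0], point), max(bounds[1], point))
    return QuantResult(point, (lo, hi), assay.replicate_counts.size, bounds=bounds, flags=flags)


def infected_abundance(fraction: float, host_abundance: float) -> float:
    """Infected cells ml^-1 = infected fraction x host abundance."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if host_abundance < 0:
        raise ValueError("host abundance must be >= 0")
    return fraction * host_abundance


def quantify_assay_table(
    assays,
    efficiencies=None,
    n_boot: int = 2000,
    seed: int = 0,
):
    """Quantify an assay table (one row per reaction) into one row per sample.

    Expected columns: ``sample_id``, ``lineage``, ``mode`` ("free" or
    "infected"), ``polonies``, plus ``volume_ml`` (free mode) or
    ``cells_sorted`` (infected mode) and optional ``free_phage_correction``.
    ``efficiencies`` maps lineage -> detection efficiency (default 1.0).
    Replicate rows of one (sample, lineage, mode) group form one assay.
    """
    import pandas as pd

    efficiencies = dict(efficiencies or {})
    rng = np.random.default_rng(seed)
    rows = []
    for (sample, lineage, mode), g in assays.groupby(["sample_id", "lineage", "mode"]):
        eff = float(efficiencies.get(lineage, 1.0))
        counts = g["polonies"].to_numpy(dtype=float)
        corr = float(g.get("free_phage_correction", pd.Series([0.0])).iloc[0])
        if mode == "free":
            assay = PolonyAssay(lineage, counts, input_volume_ml=float(g["volume_ml"].iloc[0]),
                                efficiency=eff)
            q = phage_concentration(assay, n_boot=n_boot, seed=rng)
        elif mode == "infected":
            assay = PolonyAssay(lineage, counts, cells_sorted=float(g["cells_sorted"].iloc[0]),
                                efficiency=eff, free_phage_correction=corr)
            q = infected_fraction(assay, n_boot=n_boot, seed=rng)
        else:
            raise ValueError(f"unknown assay mode {mode!r}")
        rows.append({
            "sample_id": sample, "lineage": lineage, "mode": mode,
            "estimate": q.point_estimate, "ci_lo": q.ci95[0], "ci_hi": q.ci95[1],
            "bound_lo": q.bounds[0] if q.bounds else None,
            "bound_hi": q.bounds[1] if q.bounds else None,
            "n_replicates": q.n_replicates, "flags": ";".join(q.flags),
        })
    return pd.DataFrame(rows)
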