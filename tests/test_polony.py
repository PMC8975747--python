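"""Polony quantification: efficiency/volume normalization, co-sort correction,
stage bounds, and bootstrap confidence intervals."""

import numpy as np
import pytest

from cyanotransect.polony import (
    PolonyAssay,
    bootstrap_ci,
    efficiency_sampler_from,
    free_phage_correction_from_concentration,
    infected_abundance,
    infected_fraction,
    infection_bounds,
    phage_concentration,
)


def free_assay(counts, volume=0.01, eff=1.0, **kw):
    return PolonyAssay("t4", np.asarray(counts), input_volume_ml=volume, efficiency=eff, **kw)


def cell_assay(counts, cells=1000.0, eff=1.0, **kw):
    return PolonyAssay("t4", np.asarray(counts), cells_sorted=cells, efficiency=eff, **kw)


class TestPhageConcentration:
    def test_point_estimate_arithmetic(self):
        q = phage_concentration(free_assay([100, 100], volume=0.01, eff=0.8))
        assert q.point_estimate == pytest.approx(12_500.0)

    def test_zero_counts_give_zero_with_zero_lower_bound(self):
        q = phage_concentration(free_assay([0, 0]))
        assert q.point_estimate == 0.0
        assert q.ci95[0] == 0.0

    def test_bootstrap_matches_brute_force_resampler(self):
        counts = np.array([40.0, 60.0])
        q = phage_concentration(free_assay(counts, volume=0.01, eff=1.0),
                                n_boot=100_000, seed=0, resample_counts="replicates")
        assert q.point_estimate == pytest.approx(5000.0)
        # independent brute-force resampler, 1e5 iterations
        rng = np.random.default_rng(99)
        means = counts[rng.integers(0, 2, size=(100_000, 2))].mean(axis=1) / 0.01
        lo, hi = np.quantile(means, [0.025, 0.975])
        assert q.ci95[0] == pytest.approx(lo, rel=0.02, abs=50.0)
        assert q.ci95[1] == pytest.approx(hi, rel=0.02, abs=50.0)

    def test_efficiency_and_volume_homogeneity(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 400, size=3)
            vol = rng.uniform(1e-3, 1e-1)
            eff = rng.uniform(0.2, 0.5)
            base = phage_concentration(free_assay(counts, vol, eff)).point_estimate
            assert phage_concentration(free_assay(counts, 2 * vol, eff)).point_estimate \
                == pytest.approx(base / 2)
            assert phage_concentration(free_assay(counts, vol, 2 * eff)).point_estimate \
                == pytest.approx(base / 2)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            phage_concentration(free_assay([10, 10], volume=0.0))

    def test_single_replicate_warns(self):
        with pytest.warns(UserWarning, match="replicates"):
            free_assay([10])


class TestInfectedFraction:
    def test_point_estimate_arithmetic(self):
        q = infected_fraction(cell_assay([50, 50], cells=1000, eff=0.5))
        assert q.point_estimate == pytest.approx(0.10)

    def test_correction_consuming_counts_clips_to_zero_with_flag(self):
        q = infected_fraction(cell_assay([10, 10], free_phage_correction=10.0))
        assert q.point_estimate == 0.0
        assert "correction_exceeds_counts" in q.flags

    def test_hand_computed_oracle_with_correction(self):
        q = infected_fraction(cell_assay([30, 40], cells=2000, eff=0.7,
                                         free_phage_correction=5.0))
        assert q.point_estimate == pytest.approx((35 - 5) / (2000 * 0.7))
        assert q.point_estimate == pytest.approx(0.0214, abs=5e-5)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            infected_fraction(cell_assay([10, 10], cells=0.0))

    def test_fraction_clipped_to_unit_interval(self):
        q = infected_fraction(cell_assay([5000, 5000], cells=100, eff=0.5))
        assert q.point_estimate == 1.0
        assert q.ci95[1] <= 1.0


class TestInfectionBounds:
    def test_early_late_efficiency_bounds(self):
        a = cell_assay([50, 50], cells=1000, eff=0.5)
        a.efficiency_early, a.efficiency_late = 0.4, 0.8
        assert infection_bounds(a) == pytest.approx((0.0625, 0.125))

    def test_bounds_collapse_when_efficiencies_equal(self):
        a = cell_assay([50, 50], cells=1000, eff=0.5)
        lo, hi = infection_bounds(a)
        assert lo == hi == pytest.approx(0.10)

    def test_inverted_efficiencies_rejected(self):
        with pytest.raises(ValueError):
            cell_assay([10, 10], eff=0.5, efficiency_early=0.8, efficiency_late=0.9)

    def test_bounds_bracket_point_on_random_assays(self, rng):
        for _ in range(1000):
            eff = rng.uniform(0.2, 0.9)
            early = rng.uniform(0.05, eff)
            late = rng.uniform(eff, 1.0)
            a = cell_assay(rng.integers(0, 200, size=3), cells=rng.uniform(500, 5000),
                           eff=eff, efficiency_early=early, efficiency_late=late,
                           free_phage_correction=rng.uniform(0, 5))
            q = infected_fraction(a, n_boot=1000)
            assert q.bounds[0] <= q.point_estimate <= q.bounds[1]


class TestBootstrapCi:
    def test_degenerate_assay_zero_width_interval(self):
        lo, hi = bootstrap_ci([50, 50, 50], normalizer=0.01, n_boot=1000,
                              resample_counts="replicates")
        assert lo == hi == pytest.approx(5000.0)

    def test_endpoints_converge_with_bootstrap_size(self):
        counts = [40, 55, 62, 48]
        small = bootstrap_ci(counts, 0.01, n_boot=1000, seed=1)
        large = bootstrap_ci(counts, 0.01, n_boot=100_000, seed=2)
        assert small[0] == pytest.approx(large[0], rel=0.02)
        assert small[1] == pytest.approx(large[1], rel=0.02)

    def test_seeded_determinism(self):
        a = bootstrap_ci([40, 60], 0.01, n_boot=2000, seed=3)
        b = bootstrap_ci([40, 60], 0.01, n_boot=2000, seed=3)
        assert a == b

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([40, 60], 0.01, n_boot=100)

    def test_efficiency_sampler_widens_interval(self):
        fixed = bootstrap_ci([40, 60], 0.01, n_boot=20_000, seed=4)
        sampler = efficiency_sampler_from(0.8)
        varied = bootstrap_ci([40, 60], 0.01 * 0.8, sampler, n_boot=20_000, seed=4)
        assert (varied[1] - varied[0]) > (fixed[1] - fixed[0])


def test_infected_abundance_examples():
    assert infected_abundance(0.05, 2e5) == pytest.approx(1e4)
    assert infected_abundance(0.0, 2e5) == 0.0
    assert infected_abundance(1.0, 2e5) == 2e5
    with pytest.raises(ValueError):
        infected_abundance(1.5, 2e5)


def test_quantify_assay_table_handles_both_modes():
    import pandas as pd

    from cyanotransect.polony import quantify_assay_table

    table = pd.DataFrame({
        "sample_id": [1, 1, 1, 1],
        "lineage": ["t4", "t4", "t4", "t4"],
        "mode": ["free", "free", "infected", "infected"],
        "polonies": [100, 100, 50, 50],
        "volume_ml": [0.01] * 4,
        "cells_sorted": [1000.0] * 4,
    })
    out = quantify_assay_table(table, efficiencies={"t4": 0.5})
    out = out.set_index("mode")
    assert out.loc["free", "estimate"] == pytest.approx(100 / (0.01 * 0.5))
    assert out.loc["infected", "estimate"] == pytest.approx(0.10)
    assert out.loc["free", "n_replicates"] == 2


def test_free_phage_correction_helper_scales_linearly():
    base = free_phage_correction_from_concentration(1e6, 1000, 1e-7)
    assert base == pytest.approx(100.0)
    assert free_phage_correction_from_concentration(2e6, 1000, 1e-7) == pytest.approx(2 * base)
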