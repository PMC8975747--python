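"""Hotspot detection: scaling/centering, temperature smoothing, curvature,
edge detection, latitude mapping, and regime-wise correlations."""

import numpy as np
import pandas as pd
import pytest

from cyanotransect import schema
from cyanotransect.hotspot import (
    curvature,
    detect_hotspot,
    hotspot_from_transect,
    regime_correlation,
    scale_and_center,
    smooth_by_temperature,
    temperature_to_latitude,
)


def small_table(abundance, regimes, cruise="A"):
    n = len(abundance)
    return pd.DataFrame(
        {
            schema.CRUISE: cruise,
            schema.LAT: np.linspace(25, 40, n),
            schema.TEMP: np.linspace(22, 12, n),
            schema.PHAGE_TOTAL: abundance,
            schema.REGIME: regimes,
        }
    )


class TestScaleAndCenter:
    def test_single_cruise_arithmetic(self):
        df = small_table([2.0, 4.0, 8.0], ["subtropical", "subtropical", "transition"])
        out = scale_and_center(df)
        np.testing.assert_allclose(out[schema.SCALED], [0.25, 0.5, 1.0])
        np.testing.assert_allclose(out[schema.CENTERED], [-0.125, 0.125, 0.625])

    def test_constant_abundance_centers_to_zero(self):
        df = small_table([3.0, 3.0, 3.0], ["subtropical"] * 3)
        out = scale_and_center(df)
        np.testing.assert_allclose(out[schema.CENTERED], 0.0, atol=1e-15)

    def test_centering_is_cruise_local(self):
        a = small_table([2.0, 4.0, 8.0], ["subtropical", "subtropical", "transition"], "A")
        b = small_table([10.0, 40.0], ["subtropical", "transition"], "B")
        out = scale_and_center(pd.concat([a, b], ignore_index=True))
        # hand oracle per cruise
        np.testing.assert_allclose(out[schema.CENTERED][:3], [-0.125, 0.125, 0.625])
        np.testing.assert_allclose(out[schema.CENTERED][3:], [0.0, 0.75])

    def test_scaling_equivariance_under_cruise_rescaling(self):
        df = small_table([2.0, 4.0, 8.0], ["subtropical", "subtropical", "transition"])
        out1 = scale_and_center(df)
        df2 = df.assign(**{schema.PHAGE_TOTAL: df[schema.PHAGE_TOTAL] * 37.0})
        out2 = scale_and_center(df2)
        np.testing.assert_allclose(out1[schema.CENTERED], out2[schema.CENTERED])

    def test_missing_subtropical_samples_error_names_cruise(self):
        df = small_table([1.0, 2.0], ["transition", "subpolar"], cruise="KM99")
        with pytest.raises(ValueError, match="KM99"):
            scale_and_center(df)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        t = np.linspace(10, 20, 60)
        grid, sm = smooth_by_temperature(t, np.full_like(t, 4.2))
        np.testing.assert_allclose(sm, 4.2, rtol=1e-12)

    def test_linear_profile_unchanged_in_interior(self):
        t = np.arange(10.0, 20.05, 0.1)  # samples on grid nodes
        v = 3.0 * t - 5.0
        grid, sm = smooth_by_temperature(t, v)
        interior = (grid > 11.3) & (grid < 18.7)
        np.testing.assert_allclose(sm[interior], 3.0 * grid[interior] - 5.0, rtol=1e-9)

    def test_step_profile_matches_brute_force_windowed_mean(self):
        t = np.arange(10.0, 20.05, 0.1)
        v = np.where(t < 15.0, 0.0, 1.0)
        grid, sm = smooth_by_temperature(t, v, window=2.5)
        # brute force: truncated-window mean over grid values
        interp = np.interp(grid, t, v)
        brute = np.array([
            interp[(grid >= g - 1.25 - 1e-9) & (grid <= g + 1.25 + 1e-9)].mean()
            for g in grid
        ])
        np.testing.assert_allclose(sm, brute, atol=1e-9)
        # ramp of width 2.5 °C centred on the step
        assert sm[np.searchsorted(grid, 13.7)] == pytest.approx(0.0, abs=1e-9)
        assert sm[np.searchsorted(grid, 16.3)] == pytest.approx(1.0, abs=1e-9)

    def test_span_not_exceeding_window_rejected(self):
        t = np.linspace(10, 12, 30)
        with pytest.raises(ValueError, match="span"):
            smooth_by_temperature(t, t, window=2.5)


class TestCurvature:
    def test_linear_profile_zero_curvature(self):
        v = 2.0 * np.arange(50) * 0.1 + 1.0
        c = curvature(v, 0.1)
        np.testing.assert_allclose(c[1:-1], 0.0, atol=1e-10)

    def test_quadratic_profile_constant_second_derivative(self):
        t = np.arange(0, 5, 0.1)
        a = 1.7
        c = curvature(a * t**2, 0.1)
        np.testing.assert_allclose(c[1:-1], 2 * a, rtol=1e-7)

    def test_gaussian_sign_pattern_and_zero_crossings(self):
        t = np.arange(10.0, 21.0, 0.1)
        sigma = 1.5
        c = curvature(np.exp(-((t - 15.5) ** 2) / (2 * sigma**2)), 0.1)
        inner = np.abs(t - 15.5) < sigma - 0.1
        outer = (np.abs(t - 15.5) > sigma + 0.1) & ~np.isnan(c)
        assert (c[inner] < 0).all()
        assert (c[outer] > 0).all()
        # zero crossings at center ± sigma within grid resolution
        signs = np.sign(c[1:-1])
        crossings = t[1:-1][np.flatnonzero(np.diff(signs) != 0)]
        assert np.any(np.abs(crossings - (15.5 - sigma)) <= 0.15)
        assert np.any(np.abs(crossings - (15.5 + sigma)) <= 0.15)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            curvature(np.array([1.0, 2.0]), 0.1)


class TestDetectHotspot:
    def test_noiseless_gaussian_bump_contains_center_and_symmetric(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(8, 24, 500))
        v = 0.2 + np.exp(-((t - 15.5) ** 2) / (2 * 1.5**2))
        res = detect_hotspot(t, v)
        assert res.found
        assert res.t_lo < 15.5 < res.t_hi
        assert (15.5 - res.t_lo) == pytest.approx(res.t_hi - 15.5, abs=0.3)

    def test_monotone_profile_flagged_no_hotspot(self):
        t = np.linspace(8, 24, 200)
        res = detect_hotspot(t, 0.1 * t)
        assert not res.found
        assert "no_interior_maximum" in res.flags

    def test_affine_profile_zero_curvature_everywhere_defined(self):
        t = np.linspace(8, 24, 400)
        res = detect_hotspot(t, 2.0 - 0.05 * t)
        assert not res.found
        # interior curvature is ~0 once clear of the truncated-window,
        # stencil, and curvature-smoothing edge zones (1.25 °C each)
        grid = res.grid
        inner = (grid > grid[0] + 4.0) & (grid < grid[-1] - 4.0)
        assert np.nanmax(np.abs(res.curvature[inner])) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_default_scenario_band_contains_injected_center(self, seed):
        from cyanotransect.regimes import annotate_regimes
        from cyanotransect.synthetic import TransectScenario, generate_transect

        df, truth = generate_transect(TransectScenario(seed=seed))
        res = hotspot_from_transect(annotate_regimes(df))
        assert res.found
        assert res.t_lo < truth.hotspot_center_c < res.t_hi


class TestTemperatureToLatitude:
    def test_linear_relation_inverts_exactly(self):
        lats = np.linspace(20.0, 34.0, 40)
        df = pd.DataFrame({schema.LAT: lats, schema.TEMP: 30.0 - 0.5 * lats})
        lat_lo, lat_hi, flags = temperature_to_latitude((15.0, 18.0), df, median_filter=1)
        assert lat_lo == pytest.approx(24.0, abs=1e-6)
        assert lat_hi == pytest.approx(30.0, abs=1e-6)
        assert not flags

    def test_out_of_range_temperatures_clip_with_flag(self):
        lats = np.linspace(20.0, 30.0, 20)
        df = pd.DataFrame({schema.LAT: lats, schema.TEMP: 30.0 - 0.5 * lats})
        lat_lo, lat_hi, flags = temperature_to_latitude((5.0, 40.0), df)
        assert lat_lo == pytest.approx(20.0)
        assert lat_hi == pytest.approx(30.0)
        assert flags

    def test_synthetic_band_contains_true_latitude_band(self, annotated_transect, default_survey):
        _, truth = default_survey
        res = hotspot_from_transect(annotated_transect)
        for cruise, (lat_lo, lat_hi) in res.lat_ranges.items():
            g = annotated_transect[annotated_transect[schema.CRUISE] == cruise]
            # latitude of the true bump center on this cruise
            order = np.argsort(g[schema.TEMP].to_numpy())
            lat_center = np.interp(truth.hotspot_center_c,
                                   g[schema.TEMP].to_numpy()[order],
                                   g[schema.LAT].to_numpy()[order])
            assert lat_lo <= lat_center <= lat_hi


class TestRegimeCorrelation:
    def test_identity_gives_unit_correlation(self):
        x = np.array([1.0, 10.0, 100.0, 55.0])
        r, p, n = regime_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_log_reciprocal_gives_minus_one(self):
        x = np.array([1.0, 10.0, 100.0, 55.0])
        r, _, _ = regime_correlation(x, 1e6 / x)
        assert r == pytest.approx(-1.0)

    def test_bivariate_lognormal_monte_carlo(self, rng):
        n = 10_000
        rho = 0.5
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        r, _, nn = regime_correlation(10 ** z1, 10 ** z2)
        assert r == pytest.approx(rho, abs=0.02)
        assert nn == n

    def test_nonpositive_pairs_dropped(self):
        x = np.array([0.0, 1.0, 10.0, 100.0, np.nan])
        y = np.array([5.0, 1.0, 10.0, 100.0, 3.0])
        r, _, n = regime_correlation(x, y)
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r, p, _ = regime_correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)
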