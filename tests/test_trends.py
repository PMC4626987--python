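"""Smoothing, ensemble envelopes, rates and the Monte Carlo trend test."""

import numpy as np
import pytest
import xarray as xr

from heatband.trends import (
    NO_TREND_FLAG,
    average_rate,
    ensemble_percentiles,
    monte_carlo_trend_test,
    moving_average,
    ols_slope,
    trend_map,
)


class TestMovingAverage:
    def test_constant_series_stays_constant_and_shrinks(self):
        out = moving_average(np.full(140, 50.0))
        assert out.size == 130
        np.testing.assert_allclose(out, 50.0)

    def test_linear_series_passes_through_centers(self):
        t = np.arange(100, dtype=float)
        out = moving_average(t)
        np.testing.assert_allclose(out, t[5:-5])

    def test_full_record_centers_are_1966_to_2095(self):
        """A 1961-2100 annual series smooths to valid centers 1966..2095."""
        years = np.arange(1961, 2101)
        series = xr.DataArray(
            np.random.default_rng(0).normal(size=years.size),
            dims=("year",), coords={"year": years},
        )
        out = moving_average(series)
        assert int(out["year"][0]) == 1966
        assert int(out["year"][-1]) == 2095
        assert out.sizes["year"] == years.size - 10

    def test_smoothed_values_stay_within_window_range(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 365, 60)
        out = moving_average(x)
        for k, v in enumerate(out):
            window = x[k:k + 11]
            assert window.min() <= v <= window.max()

    def test_short_series_and_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(5.0))
        with pytest.raises(ValueError):
            moving_average(np.arange(50.0), window=10)


class TestEnsemblePercentiles:
    def _members(self, values):
        arr = np.asarray(values, dtype=float)
        return xr.DataArray(
            arr, dims=("member", "year"),
            coords={"year": np.arange(1961, 1961 + arr.shape[1])},
        )

    def test_degenerate_identical_members(self):
        env = ensemble_percentiles(self._members([[7.0] * 5] * 4))
        for k in ("p10", "median", "p90"):
            np.testing.assert_allclose(env[k].values, 7.0)

    def test_two_member_median_is_midpoint(self):
        env = ensemble_percentiles(self._members([[0.0] * 3, [10.0] * 3]))
        np.testing.assert_allclose(env["median"].values, 5.0)

    def test_six_members_match_sort_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 365, (6, 8))
        env = ensemble_percentiles(self._members(vals))
        for yi in range(8):
            s = np.sort(vals[:, yi])
            # median of six = mean of 3rd and 4th order statistics
            assert env["median"].values[yi] == pytest.approx((s[2] + s[3]) / 2)
            for key, q in (("p10", 10), ("p90", 90)):
                assert env[key].values[yi] == pytest.approx(
                    np.percentile(vals[:, yi], q, method="linear")
                )

    def test_envelope_ordering_every_year(self):
        rng = np.random.default_rng(3)
        env = ensemble_percentiles(self._members(rng.uniform(0, 365, (6, 50))))
        assert np.all(env["p10"].values <= env["median"].values)
        assert np.all(env["median"].values <= env["p90"].values)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            ensemble_percentiles(self._members([[1.0, 2.0]]))


class TestAverageRate:
    def test_constant_series_has_zero_rate(self):
        assert average_rate(np.full(130, 42.0)) == 0.0

    def test_linear_input_recovers_slope_under_difference_convention(self):
        b = 1.7
        smoothed = moving_average(b * np.arange(140, dtype=float))
        assert average_rate(smoothed, denominator="difference") == pytest.approx(b)
        # the inclusive convention divides by n rather than n-1
        assert average_rate(smoothed, denominator="inclusive") == pytest.approx(
            b * 129 / 130
        )

    def test_inclusive_denominator_is_130_for_full_record(self):
        smoothed = np.zeros(130)
        smoothed[-1] = 130.0
        assert average_rate(smoothed, denominator="inclusive") == pytest.approx(1.0)
        assert average_rate(smoothed, denominator="difference") == pytest.approx(
            130.0 / 129.0
        )

    def test_rate_ordering_preserved_across_cells(self):
        """Steeper generating trends yield larger average rates (the ordering
        of fast vs moderate cities is structural)."""
        rng = np.random.default_rng(4)
        rates = []
        for b in (1.10, 1.98, 2.36):
            series = b * np.arange(140) + rng.normal(0, 3, 140)
            rates.append(average_rate(moving_average(series)))
        assert rates[0] < rates[1] < rates[2]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            average_rate(np.array([1.0]))


class TestMonteCarloTrendTest:
    def test_strictly_increasing_series_significant_everywhere(self):
        res = monte_carlo_trend_test(np.arange(1, 132, dtype=float), n_iter=100, seed=0)
        assert res.significant == {90: True, 95: True, 99: True}
        assert res.slope == pytest.approx(1.0)
        assert res.flag == 99

    def test_constant_series_flagged_no_trend(self):
        res = monte_carlo_trend_test(np.full(50, 5.0), n_iter=100, seed=0)
        assert res.slope == 0.0 and res.no_trend_possible
        assert res.flag == NO_TREND_FLAG
        assert not any(res.significant.values())

    def test_seeded_reproducibility(self):
        y = np.random.default_rng(5).normal(size=60)
        a = monte_carlo_trend_test(y, seed=42)
        b = monte_carlo_trend_test(y, seed=42)
        assert a.rank == b.rank and a.significant == b.significant

    def test_significance_nesting(self):
        """99% significance implies 95% and 90% (one-sided percentiles nest)."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            y = rng.normal(0, 1, 40) + rng.uniform(0, 0.1) * np.arange(40)
            res = monte_carlo_trend_test(y, n_iter=200, seed=rng.integers(2**31))
            if res.significant[99]:
                assert res.significant[95] and res.significant[90]
            if res.significant[95]:
                assert res.significant[90]

    def test_two_sided_detects_decreasing_trend(self):
        y = -np.arange(131, dtype=float)
        one = monte_carlo_trend_test(y, seed=0, alternative="increasing")
        two = monte_carlo_trend_test(y, seed=0, alternative="two-sided")
        assert not one.significant[95]
        assert two.significant[95]

    def test_power_monotone_in_trend_magnitude(self):
        """Rejection fraction does not decrease over a 3-point trend grid."""
        rng = np.random.default_rng(7)
        n, reps = 60, 40
        power = []
        for b in (0.0, 0.02, 0.08):
            hits = 0
            for _ in range(reps):
                y = b * np.arange(n) + rng.normal(0, 1, n)
                hits += monte_carlo_trend_test(
                    y, n_iter=200, seed=rng.integers(2**31)
                ).significant[95]
            power.append(hits / reps)
        assert power[0] <= power[1] + 0.1 and power[1] <= power[2] + 0.1
        assert power[2] > power[0]

    def test_block_bootstrap_runs_and_is_reproducible(self):
        y = np.random.default_rng(8).normal(size=60)
        a = monte_carlo_trend_test(y, seed=1, block_length=5)
        b = monte_carlo_trend_test(y, seed=1, block_length=5)
        assert a.rank == b.rank

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_trend_test(np.arange(5.0))


class TestTrendMap:
    def _counts(self, data, years=None):
        ny, nlat, nlon = data.shape
        years = np.arange(1961, 1961 + ny) if years is None else years
        return xr.DataArray(
            data, dims=("year", "lat", "lon"),
            coords={"year": years, "lat": np.arange(nlat, dtype=float),
                    "lon": np.arange(nlon, dtype=float)},
        )

    def test_saturated_grid_flagged_no_trend_possible(self):
        counts = self._counts(np.full((40, 2, 2), 365.0))
        tm = trend_map(counts, n_iter=100, seed=0)
        assert np.all(tm["significance"].values == NO_TREND_FLAG)
        np.testing.assert_allclose(tm["rate"].values, 0.0)

    def test_injected_trends_detected_noise_cells_near_nominal_rate(self):
        """Trended cells are flagged at 99%; on raw (unsmoothed) iid noise
        cells the 95% false-positive fraction stays near nominal. The
        calibration is checked unsmoothed because the iid bootstrap null is
        deliberately anti-conservative on smoothed series."""
        rng = np.random.default_rng(9)
        ny, n_noise = 60, 40
        data = np.empty((ny, 2, n_noise))
        data[:, 0, :] = 3.0 * np.arange(ny)[:, None] + rng.normal(0, 2, (ny, n_noise))
        data[:, 1, :] = rng.normal(100, 2, (ny, n_noise))  # stationary noise
        tm = trend_map(self._counts(data), n_iter=300, seed=1, smooth=False)
        assert np.all(tm["significance"].values[0, :] == 99)
        false_pos = np.mean(tm["significance"].values[1, :] >= 95)
        assert false_pos <= 0.2  # binomial slack around the nominal 5%

    def test_single_cell_reduces_to_series_test(self):
        rng = np.random.default_rng(10)
        series = 2.0 * np.arange(50) + rng.normal(0, 1, 50)
        tm = trend_map(self._counts(series[:, None, None]), n_iter=200, seed=3)
        sm = moving_average(series)
        assert tm["rate"].values[0, 0] == pytest.approx(average_rate(sm))
        child = np.random.SeedSequence(3).spawn(1)[0]
        res = monte_carlo_trend_test(
            sm, n_iter=200, seed=np.random.default_rng(child)
        )
        assert int(tm["significance"].values[0, 0]) == res.flag
        assert tm["rank"].values[0, 0] == pytest.approx(res.rank)


def test_ols_slope_matches_polyfit():
    rng = np.random.default_rng(11)
    y = rng.normal(size=37) + 0.3 * np.arange(37)
    assert ols_slope(y) == pytest.approx(np.polyfit(np.arange(37), y, 1)[0])
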