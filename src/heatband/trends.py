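"""Trend characterization of annual hot-day series.

The pipeline order is: smooth each cell's annual count series with a
centered 11-year moving average, summarize the ensemble with per-year 10th /
50th / 90th percentiles, estimate the average rate of increase from the
smoothed ensemble-median series, and assess trend significance with a Monte
Carlo re-randomization test (value bootstrap: the series is resampled with
replacement, destroying temporal order; the OLS slope of each resampled
series forms the null distribution, and the observed slope is ranked
against it).

Conventions, fixed and exposed as flags because they change the numbers:

* ``denominator="inclusive"`` (default) divides the end-minus-start change in
  the smoothed series by the inclusive count of center years — 130 for
  centers 1966-2095 from a 1961-2100 record. ``"difference"`` uses the plain
  year difference (129), which recovers the generating slope exactly on
  linear input.
* Ensemble percentiles use linear interpolation between order statistics
  (the 10th/90th percentiles of six members are interpolation-sensitive).
* The test is one-sided (increasing) by default; significance at level L
  requires the observed slope to STRICTLY exceed the L-th percentile of the
  null slopes, so ties are conservative.
* The iid value bootstrap ignores the autocorrelation the smoothing
  introduces and is therefore anti-conservative on smoothed series; a moving
  block bootstrap is available through ``block_length``.

No field-significance or multiple-testing correction is applied across grid
cells; per-cell flags are marginal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

DEFAULT_WINDOW = 11
DEFAULT_LEVELS = (90, 95, 99)
NO_TREND_FLAG = -1


def moving_average(series, window: int = DEFAULT_WINDOW, dim: str = "year"):
    """Centered unweighted moving average; edge years without a full window
    are dropped, so the output is (window - 1) shorter.

    Accepts a 1-D numpy array or an xarray object with dimension ``dim``
    (extra dims are smoothed cell-wise).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if isinstance(series, (xr.DataArray, xr.Dataset)):
        if series.sizes[dim] < window:
            raise ValueError(
                f"series length {series.sizes[dim]} shorter than window {window}"
            )
        half = window // 2
        sm = series.rolling({dim: window}, center=True).mean()
        return sm.isel({dim: slice(half, series.sizes[dim] - half)})
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("numpy input must be 1-D")
    if arr.size < window:
        raise ValueError(f"series length {arr.size} shorter than window {window}")
    return np.convolve(arr, np.full(window, 1.0 / window), mode="valid")


def ensemble_percentiles(
    members: xr.DataArray, probs: tuple[float, ...] = (10, 50, 90),
    dim: str = "member",
) -> xr.Dataset:
    """Per-year order statistics across ensemble members.

    Linear interpolation between order statistics; the median of six members
    is the mean of the 3rd and 4th. Requires >= 2 members on aligned years.
    """
    if members.sizes.get(dim, 0) < 2:
        raise ValueError("need at least 2 ensemble members")
    pct = members.quantile([p / 100.0 for p in probs], dim=dim, method="linear")
    names = {0.10: "p10", 0.50: "median", 0.90: "p90"}
    out = xr.Dataset(
        {
            names.get(q, f"p{int(round(q * 100))}"): pct.sel(quantile=q).drop_vars("quantile")
            for q in pct["quantile"].values
        }
    )
    return out


def average_rate(
    smoothed, dim: str = "year", denominator: str = "inclusive"
):
    """Average rate of change (days/year) of a smoothed series.

    (last center value - first center value) divided by the span of center
    years: the inclusive year count (last - first + 1) by default, or the
    plain difference (last - first) with ``denominator="difference"``.
    """
    if denominator not in ("inclusive", "difference"):
        raise ValueError("denominator must be 'inclusive' or 'difference'")
    if isinstance(smoothed, (xr.DataArray, xr.Dataset)):
        n = smoothed.sizes[dim]
        if n < 2:
            raise ValueError("need at least 2 valid centers")
        first = smoothed.isel({dim: 0})
        last = smoothed.isel({dim: -1})
        span = n if denominator == "inclusive" else n - 1
        return (last - first) / span
    arr = np.asarray(smoothed, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 valid centers")
    span = arr.size if denominator == "inclusive" else arr.size - 1
    return (arr[-1] - arr[0]) / span


def ols_slope(y: np.ndarray) -> float:
    """Ordinary least-squares slope of y against 0..n-1."""
    y = np.asarray(y, dtype=float)
    x = np.arange(y.size, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


@dataclass
class TrendResult:
    """Outcome of the Monte Carlo trend test on one series."""

    slope: float  # OLS slope, days/year
    rank: float  # fraction of null slopes strictly below the observed slope
    significant: dict[int, bool]  # level (%) -> flag
    n_iterations: int
    seed: int | None
    no_trend_possible: bool = False

    @property
    def flag(self) -> int:
        """Highest attained level, 0 if none, -1 if no trend is possible."""
        if self.no_trend_possible:
            return NO_TREND_FLAG
        attained = [lvl for lvl, sig in self.significant.items() if sig]
        return max(attained) if attained else 0


def monte_carlo_trend_test(
    series,
    n_iter: int = 1000,
    seed: int | np.random.Generator | None = None,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
    alternative: str = "increasing",
    block_length: int = 1,
) -> TrendResult:
    """Re-randomization significance test for a monotone trend.

    The null distribution is built from ``n_iter`` series resampled with
    replacement from the observed values (``block_length`` > 1 resamples
    moving blocks instead, preserving short-range autocorrelation). The
    observed OLS slope is significant at level L when it strictly exceeds
    the L-th percentile of the null slopes (one-sided increasing); with
    ``alternative="two-sided"`` absolute slopes are compared.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("series too short for a trend test (need >= 10)")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if alternative not in ("increasing", "two-sided"):
        raise ValueError("alternative must be 'increasing' or 'two-sided'")

    seed_out = seed if isinstance(seed, (int, type(None))) else None
    if np.ptp(y) == 0.0:  # constant series: zero slope, nothing to resample
        return TrendResult(0.0, 0.0, {lvl: False for lvl in levels}, n_iter,
                           seed_out, no_trend_possible=True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.arange(n, dtype=float)
    xc = x - x.mean()
    w = xc / (xc @ xc)  # slope(y) = w @ y (intercept drops out)
    slope = float(w @ y)

    if block_length <= 1:
        idx = rng.integers(0, n, size=(n_iter, n))
    else:
        n_blocks = -(-n // block_length)
        starts = rng.integers(0, n - block_length + 1, size=(n_iter, n_blocks))
        offsets = np.arange(block_length)
        idx = (starts[:, :, None] + offsets).reshape(n_iter, -1)[:, :n]
    null = y[idx] @ w

    stat, null_stat = (slope, null) if alternative == "increasing" else (
        abs(slope), np.abs(null))
    significant = {
        lvl: bool(stat > np.percentile(null_stat, lvl)) for lvl in levels
    }
    rank = float(np.mean(null_stat < stat))
    return TrendResult(slope, rank, significant, n_iter, seed_out)


def trend_map(
    counts: xr.DataArray,
    window: int = DEFAULT_WINDOW,
    n_iter: int = 1000,
    seed: int | None = None,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
    denominator: str = "inclusive",
    alternative: str = "increasing",
    smooth: bool = True,
) -> xr.Dataset:
    """Cell-wise smoothing, average rate and Monte Carlo significance.

    ``counts`` is an ensemble-median annual count series on (year, lat, lon).
    Cells whose smoothed series is constant (e.g. already at 365 days/year or
    at 0 throughout) are flagged ``-1`` (no trend possible) rather than
    non-significant. Each cell gets an independent child RNG spawned from
    ``seed``, so results do not depend on traversal order.
    """
    ny, nlat, nlon = (counts.sizes[d] for d in ("year", "lat", "lon"))
    rate = np.empty((nlat, nlon))
    flag = np.empty((nlat, nlon), dtype=np.int32)
    rankarr = np.full((nlat, nlon), np.nan)
    children = np.random.SeedSequence(seed).spawn(nlat * nlon)

    values = counts.transpose("year", "lat", "lon").values.astype(float)
    for i in range(nlat):
        for j in range(nlon):
            series = values[:, i, j]
            sm = moving_average(series, window) if smooth else series
            rate[i, j] = average_rate(sm, denominator=denominator)
            res = monte_carlo_trend_test(
                sm,
                n_iter=n_iter,
                seed=np.random.default_rng(children[i * nlon + j]),
                levels=levels,
                alternative=alternative,
            )
            flag[i, j] = res.flag
            rankarr[i, j] = res.rank

    coords = {"lat": counts["lat"].values, "lon": counts["lon"].values}
    out = xr.Dataset(
        {
            "rate": xr.DataArray(rate, dims=("lat", "lon"), coords=coords,
                                 attrs={"units": "days/year"}),
            "significance": xr.DataArray(flag, dims=("lat", "lon"), coords=coords,
                                         attrs={"flags": "0 none, 90/95/99 level, -1 no trend possible"}),
            "rank": xr.DataArray(rankarr, dims=("lat", "lon"), coords=coords),
        },
        attrs={
            "window": window, "n_iter": n_iter,
            "seed": -1 if seed is None else seed,
            "denominator": denominator, "alternative": alternative,
        },
    )
    return out
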