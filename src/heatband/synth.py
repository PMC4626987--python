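"""Synthetic gridded daily climate ensembles with known ground truth.

Emulates the statistical surface of a downscaled regional-climate ensemble:
six members over 1961-2100 with a hemisphere-aware seasonal cycle, a
spatially varying secular warming trend, spatially varying relative humidity,
systematic (calendar-month) model biases in temperature and humidity, and
day-to-day noise. A matching bias-free reference climatology plays the role
of the observed monthly dataset the bias correction is anchored to.

The generative model per member, day d in year y at cell (i, j):

    tmax_true = t_base(i) + A * cos(2*pi*(doy - peak(i))/365)
                + trend(i,j) * elapsed/100
    tmax_model = tmax_true + bias_t[month] + eta_t          (eta_t ~ AR(1))
    rh_true    = clip(rh_base(i,j) + rh_trend * elapsed/100, 0, 100)
    rh_model   = clip(rh_true * bias_rh[month] + eta_rh, 0, 100)
    wind       = max(wind_mean + eta_w, 0)        (no bias, no trend)

where elapsed is years since the start of the record (fractional, so the
trend accrues within years too) and peak(i) puts the seasonal maximum in
mid-July north of the equator and mid-January south of it. Noise is
independent across cells and members; temporal AR(1) autocorrelation is
available through ``ar1`` (default 0, i.e. white noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import xarray as xr
from scipy.signal import lfilter

from .timeaxis import (
    DAYS_PER_YEAR,
    MONTH_OF_DOY,
    make_daily_field,
    time_coords,
    year_range,
)

_PEAK_DOY_NORTH = 196  # mid-July
_PEAK_DOY_SOUTH = 15  # mid-January


def _as_monthly(x, name: str) -> np.ndarray:
    """Broadcast a scalar or length-12 sequence to a per-month vector."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return np.full(12, float(arr))
    if arr.shape != (12,):
        raise ValueError(f"{name} must be a scalar or length-12 sequence")
    return arr


def _as_grid(x, n_lat: int, n_lon: int, name: str) -> np.ndarray:
    """Broadcast a scalar, (n_lat,) profile or (n_lat, n_lon) field to the grid."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return np.full((n_lat, n_lon), float(arr))
    if arr.ndim == 1:
        if arr.shape != (n_lat,):
            raise ValueError(f"{name}: 1-D value must have length n_lat={n_lat}")
        return np.broadcast_to(arr[:, None], (n_lat, n_lon)).copy()
    if arr.shape != (n_lat, n_lon):
        raise ValueError(f"{name}: 2-D value must have shape ({n_lat}, {n_lon})")
    return arr.copy()


@dataclass
class SynthConfig:
    """Parameters of the synthetic ensemble; defaults are the study conditions.

    Spatial fields (``t_base``, ``trend_degC_per_century``, ``rh_base``) may
    be scalars, or arrays broadcastable to (n_lat,) / (n_lat, n_lon). When
    left ``None`` they default to smooth latitude-dependent profiles: warm
    humid equator, cooler drier subtropics.
    """

    n_members: int = 6
    year_start: int = 1961
    year_end: int = 2100
    n_lat: int = 10
    n_lon: int = 10
    lat_start: float = -35.0
    lon_start: float = 10.0
    dlat: float = 6.0
    dlon: float = 4.0
    t_base: float | np.ndarray | None = None  # deg C annual mean Tmax
    t_seasonal_amp: float = 6.0  # deg C half-range of seasonal cycle
    trend_degC_per_century: float | np.ndarray = 3.0
    rh_base: float | np.ndarray | None = None  # %
    rh_trend_per_century: float = 0.0  # % per 100 yr
    wind_mean: float = 3.0  # m/s
    wind_sd: float = 1.0  # m/s
    bias_t: float | np.ndarray = 0.0  # additive, deg C, scalar or per month
    bias_rh: float | np.ndarray = 1.0  # multiplicative, scalar or per month
    noise_sd_t: float = 1.0  # deg C
    noise_sd_rh: float = 5.0  # %
    ar1: float = 0.0  # lag-1 autocorrelation of the noise
    seed: int = 0
    baseline: tuple[int, int] = (1961, 1990)

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        if self.n_lat < 1 or self.n_lon < 1 or self.dlat <= 0 or self.dlon <= 0:
            raise ValueError("invalid grid")
        if not -1 < self.ar1 < 1:
            raise ValueError("ar1 must lie in (-1, 1)")

    @property
    def lat(self) -> np.ndarray:
        return self.lat_start + self.dlat * np.arange(self.n_lat)

    @property
    def lon(self) -> np.ndarray:
        return self.lon_start + self.dlon * np.arange(self.n_lon)

    def t_base_grid(self) -> np.ndarray:
        """(n_lat, n_lon) baseline annual-mean Tmax: warm equator, cooler poleward."""
        base = 30.0 - 0.22 * np.abs(self.lat) if self.t_base is None else self.t_base
        return _as_grid(base, self.n_lat, self.n_lon, "t_base")

    def rh_base_grid(self) -> np.ndarray:
        """(n_lat, n_lon) baseline RH: humid equator, drier subtropics."""
        base = (
            np.clip(80.0 - 0.8 * np.abs(self.lat), 20.0, 95.0)
            if self.rh_base is None
            else self.rh_base
        )
        return _as_grid(base, self.n_lat, self.n_lon, "rh_base")

    def trend_grid(self) -> np.ndarray:
        return _as_grid(self.trend_degC_per_century, self.n_lat, self.n_lon,
                        "trend_degC_per_century")


@dataclass
class EnsembleSet:
    """Member-labelled bundles of daily tmax/rh/wind fields."""

    members: dict[str, xr.Dataset] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.items())

    def __getitem__(self, key: str) -> xr.Dataset:
        return self.members[key]


def _seasonal_cycle(config: SynthConfig) -> np.ndarray:
    """(365, n_lat) seasonal anomaly; peak flips hemisphere with latitude."""
    doy = np.arange(1, DAYS_PER_YEAR + 1)[:, None]
    peak = np.where(config.lat < 0, _PEAK_DOY_SOUTH, _PEAK_DOY_NORTH)[None, :]
    return config.t_seasonal_amp * np.cos(2 * np.pi * (doy - peak) / DAYS_PER_YEAR)


def _true_fields(config: SynthConfig, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bias-free, noise-free daily (tmax, rh) over the given years."""
    n_days = years.size * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), years.size)
    yr = np.repeat(years, DAYS_PER_YEAR)
    elapsed = (yr - config.year_start) + (doy - 0.5) / DAYS_PER_YEAR

    seasonal = _seasonal_cycle(config)  # (365, n_lat)
    seasonal_full = np.tile(seasonal, (years.size, 1))[:, :, None]  # (t, lat, 1)

    tmax = (
        config.t_base_grid()[None, :, :]
        + seasonal_full
        + config.trend_grid()[None, :, :] * (elapsed[:, None, None] / 100.0)
    )
    rh = np.clip(
        config.rh_base_grid()[None, :, :]
        + config.rh_trend_per_century * (elapsed[:, None, None] / 100.0),
        0.0,
        100.0,
    )
    assert tmax.shape == (n_days, config.n_lat, config.n_lon)
    return tmax, rh


def _ar1_noise(rng: np.random.Generator, sd: float, shape: tuple, ar1: float) -> np.ndarray:
    """AR(1) noise along axis 0 with stationary marginal sd."""
    eps = rng.standard_normal(shape)
    if ar1 == 0.0:
        return sd * eps
    innov = np.sqrt(1.0 - ar1 * ar1) * eps
    innov[0] = eps[0]  # stationary start: x0 ~ N(0, 1)
    x = lfilter([1.0], [1.0, -ar1], innov, axis=0)
    return sd * x


def generate_member(config: SynthConfig, rng: np.random.Generator) -> xr.Dataset:
    """One ensemble member: biased, noisy daily tmax (degC), rh (%), wind (m/s)."""
    years = year_range(config.year_start, config.year_end)
    tmax_true, rh_true = _true_fields(config, years)
    shape = tmax_true.shape

    month = np.tile(MONTH_OF_DOY, years.size)  # month of each day
    bias_t = _as_monthly(config.bias_t, "bias_t")[month - 1][:, None, None]
    bias_rh = _as_monthly(config.bias_rh, "bias_rh")[month - 1][:, None, None]

    tmax = tmax_true + bias_t + _ar1_noise(rng, config.noise_sd_t, shape, config.ar1)
    rh = np.clip(
        rh_true * bias_rh + _ar1_noise(rng, config.noise_sd_rh, shape, config.ar1),
        0.0,
        100.0,
    )
    wind = np.maximum(config.wind_mean + config.wind_sd * rng.standard_normal(shape), 0.0)

    kw = dict(lat=config.lat, lon=config.lon,
              year_start=config.year_start, year_end=config.year_end)
    ds = xr.Dataset(
        {
            "tmax": make_daily_field(tmax.astype(np.float32), "tmax", "degC", **kw),
            "rh": make_daily_field(rh.astype(np.float32), "rh", "%", **kw),
            "wind": make_daily_field(wind.astype(np.float32), "wind", "m s-1", **kw),
        }
    )
    ds.attrs["calendar"] = "365_day"
    return ds


def generate_ensemble(config: SynthConfig) -> EnsembleSet:
    """Generate all members; reproducible given ``config.seed``.

    Each member gets an independent child RNG spawned from the seed, so the
    set is reproducible as a whole and members are mutually independent.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_members)
    members = {
        f"member{m + 1}": generate_member(config, np.random.default_rng(children[m]))
        for m in range(config.n_members)
    }
    return EnsembleSet(members)


def generate_reference_climatology(config: SynthConfig) -> xr.Dataset:
    """Bias-free monthly-mean tmax and rh over the baseline period.

    This is the 'truth' the bias correction should restore: the 12 monthly
    means implied by the configured base state, seasonal cycle and trend over
    the baseline years, with no model bias and no noise.
    """
    y0, y1 = config.baseline
    years = year_range(y0, y1)
    tmax_true, rh_true = _true_fields(config, years)
    month = np.tile(MONTH_OF_DOY, years.size)

    tm = np.empty((12, config.n_lat, config.n_lon))
    rm = np.empty_like(tm)
    for m in range(1, 13):
        sel = month == m
        tm[m - 1] = tmax_true[sel].mean(axis=0)
        rm[m - 1] = rh_true[sel].mean(axis=0)

    coords = {"month": np.arange(1, 13, dtype=np.int32),
              "lat": config.lat, "lon": config.lon}
    ds = xr.Dataset(
        {
            "tmax": xr.DataArray(tm, dims=("month", "lat", "lon"), coords=coords,
                                 attrs={"units": "degC"}),
            "rh": xr.DataArray(rm, dims=("month", "lat", "lon"), coords=coords,
                               attrs={"units": "%"}),
        },
        attrs={"baseline": f"{y0}-{y1}"},
    )
    return ds
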