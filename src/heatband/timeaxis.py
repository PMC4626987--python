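"""365-day (no-leap) calendar helpers.

The whole pipeline runs on a fixed 365-day calendar, the common convention
for climate-model output: every year has 365 days, February always has 28.
Time is an integer day index from the first day of the first simulated year;
``year``, ``month`` and ``dayofyear`` ride along as auxiliary coordinates so
that month/year group-bys never touch datetime machinery.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

DAYS_PER_YEAR = 365
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_OF_DOY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)  # day-of-year -> month

CALENDAR_ATTR = "365_day"


def year_range(year_start: int, year_end: int) -> np.ndarray:
    """Inclusive range of years as an int array; validates non-emptiness."""
    if year_end < year_start:
        raise ValueError(f"empty year range {year_start}-{year_end}")
    return np.arange(year_start, year_end + 1)


def time_coords(year_start: int, year_end: int) -> dict:
    """Coordinate dict for a daily (time,) axis spanning the years inclusively.

    Returns ``time`` (integer day index), ``year``, ``month`` and
    ``dayofyear`` auxiliary coordinates, suitable for passing to
    :class:`xarray.DataArray`.
    """
    years = year_range(year_start, year_end)
    n = years.size * DAYS_PER_YEAR
    return {
        "time": np.arange(n, dtype=np.int32),
        "year": ("time", np.repeat(years, DAYS_PER_YEAR).astype(np.int32)),
        "month": ("time", np.tile(MONTH_OF_DOY, years.size).astype(np.int32)),
        "dayofyear": ("time", np.tile(np.arange(1, DAYS_PER_YEAR + 1), years.size).astype(np.int32)),
    }


def make_daily_field(
    data: np.ndarray,
    name: str,
    units: str,
    lat: np.ndarray,
    lon: np.ndarray,
    year_start: int,
    year_end: int,
) -> xr.DataArray:
    """Wrap a (time, lat, lon) array as a DataArray with calendar metadata."""
    coords = time_coords(year_start, year_end)
    n_days = coords["time"].size
    if data.shape != (n_days, lat.size, lon.size):
        raise ValueError(
            f"data shape {data.shape} does not match "
            f"(time={n_days}, lat={lat.size}, lon={lon.size})"
        )
    da = xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={**coords, "lat": lat.astype(np.float64), "lon": lon.astype(np.float64)},
        name=name,
        attrs={"units": units, "calendar": CALENDAR_ATTR},
    )
    da["lat"].attrs.update(units="degrees_north", axis="Y")
    da["lon"].attrs.update(units="degrees_east", axis="X")
    return da


def field_years(field: xr.DataArray) -> np.ndarray:
    """Distinct years present on a daily field, in order."""
    return np.unique(field["year"].values)


def check_full_years(field: xr.DataArray, years: np.ndarray) -> None:
    """Raise if any requested year is absent or incomplete (< 365 days)."""
    yr = field["year"].values
    counts = {int(y): int((yr == y).sum()) for y in years}
    missing = [y for y, c in counts.items() if c == 0]
    partial = [y for y, c in counts.items() if 0 < c < DAYS_PER_YEAR]
    if missing:
        raise ValueError(f"field does not cover years: {missing}")
    if partial:
        raise ValueError(f"field has incomplete years: {partial}")
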