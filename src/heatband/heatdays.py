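"""Hot-day counting against apparent-temperature symptom thresholds.

Days are classified by daily maximum apparent temperature against the US
National Weather Service caution-chart thresholds:

    Hda1: ATmax <  27 degC          Band I   (Caution):          [27, 32)
    Hda2: ATmax >= 27 degC          Band II  (Extreme caution):  [32, 39)
    Hda3: ATmax >= 32 degC          Band III (Danger):           [39, 51)
    Hda4: ATmax >= 39 degC          Band IV  (Extreme danger):   [51, inf)
    Hda5: ATmax >= 51 degC

Hda categories are cumulative (nested: Hda2 >= Hda3 >= Hda4 >= Hda5) while
the bands partition [27, inf). All thresholds are inclusive on the left;
band upper edges are exclusive. Counts use calendar years on the 365-day
calendar; conservation (Hda1 + Hda2 = 365, sum of bands = Hda2) and nesting
are asserted for every cell-year on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .timeaxis import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

HDA_LABELS = ("Hda1", "Hda2", "Hda3", "Hda4", "Hda5")
BAND_LABELS = ("BandI", "BandII", "BandIII", "BandIV")


@dataclass(frozen=True)
class ThresholdScheme:
    """Left-inclusive AT thresholds (degC) for the cumulative Hda categories.

    Band edges are derived from consecutive thresholds; the last band is
    unbounded above.
    """

    thresholds: tuple[float, ...] = (27.0, 32.0, 39.0, 51.0)

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds) or len(self.thresholds) != 4:
            raise ValueError("thresholds must be 4 increasing values")

    @property
    def band_edges(self) -> tuple[tuple[float, float], ...]:
        t = self.thresholds
        return tuple(zip(t, (*t[1:], np.inf)))


DEFAULT_SCHEME = ThresholdScheme()


def classify_day(atmax: float, scheme: ThresholdScheme = DEFAULT_SCHEME):
    """Categories of a single day: (set of Hda labels, band label or None).

    A day below the first threshold is Hda1 with no band; otherwise it joins
    every Hda category whose threshold it meets and exactly one band.
    """
    if not np.isfinite(atmax):
        return set(), None
    if atmax < scheme.thresholds[0]:
        return {"Hda1"}, None
    hda = {
        HDA_LABELS[k + 1]
        for k, thr in enumerate(scheme.thresholds)
        if atmax >= thr
    }
    band = None
    for label, (lo, hi) in zip(BAND_LABELS, scheme.band_edges):
        if lo <= atmax < hi:
            band = label
            break
    return hda, band


def _check_invariants(counts: xr.Dataset) -> None:
    hda = [counts[k].values for k in HDA_LABELS]
    bands = [counts[k].values for k in BAND_LABELS]
    if not np.array_equal(hda[0] + hda[1], np.full_like(hda[0], DAYS_PER_YEAR)):
        raise RuntimeError("conservation violated: Hda1 + Hda2 != days-in-year")
    if not np.array_equal(sum(bands), hda[1]):
        raise RuntimeError("conservation violated: sum of bands != Hda2")
    for a, b in zip(hda[1:], hda[2:]):
        if np.any(a < b):
            raise RuntimeError("nesting violated: Hda counts not monotone")


def annual_counts(
    atmax: xr.DataArray, scheme: ThresholdScheme = DEFAULT_SCHEME
) -> xr.Dataset:
    """Per-year, per-cell day counts for Hda1-Hda5 and Bands I-IV.

    Years with any missing or absent day at any cell are excluded with a
    warning (a partial year would bias the counts). Returns a Dataset with
    dims (year, lat, lon) and int32 variables.
    """
    yr = atmax["year"].values
    years, n_days = np.unique(yr, return_counts=True)
    complete = np.ones(years.size, dtype=bool)
    # a year is eligible only if all 365 days are present and finite everywhere
    finite_per_year = np.isfinite(atmax).groupby("year").sum("time")
    for i, (y, n) in enumerate(zip(years, n_days)):
        if n < DAYS_PER_YEAR or int(finite_per_year.sel(year=y).min()) < DAYS_PER_YEAR:
            complete[i] = False
    if not complete.all():
        excluded = [int(y) for y in years[~complete]]
        logger.warning("excluding incomplete years: %s", excluded)
        atmax = atmax.where(~atmax["year"].isin(excluded), drop=True)

    data = {}
    t0 = scheme.thresholds[0]
    data["Hda1"] = (atmax < t0).groupby("year").sum("time")
    for label, thr in zip(HDA_LABELS[1:], scheme.thresholds):
        data[label] = (atmax >= thr).groupby("year").sum("time")
    for label, (lo, hi) in zip(BAND_LABELS, scheme.band_edges):
        data[label] = ((atmax >= lo) & (atmax < hi)).groupby("year").sum("time")

    counts = xr.Dataset({k: v.astype(np.int32) for k, v in data.items()})
    counts.attrs["thresholds_degC"] = list(scheme.thresholds)
    _check_invariants(counts)
    return counts


def timeslice_mean(counts: xr.Dataset, years: tuple[int, int]) -> xr.Dataset:
    """Per-cell mean days/year over an inclusive year slice.

    Raises if the slice is not fully covered by the count record.
    """
    y0, y1 = years
    have = counts["year"].values
    wanted = np.arange(y0, y1 + 1)
    missing = sorted(set(wanted) - set(have))
    if missing:
        raise ValueError(f"time slice {y0}-{y1} not covered; missing years {missing}")
    out = counts.sel(year=slice(y0, y1)).mean("year")
    out.attrs["slice"] = f"{y0}-{y1}"
    return out


def ensemble_mean(slices: list[xr.Dataset]) -> xr.Dataset:
    """Ensemble average of per-member time-slice means (mean of member means)."""
    if not slices:
        raise ValueError("no members given")
    out = xr.concat(slices, dim="member").mean("member")
    out.attrs.update(slices[0].attrs)
    return out


def change_map(future: xr.Dataset, baseline: xr.Dataset) -> xr.Dataset:
    """Future minus baseline mean days/year, per cell and category."""
    if not (
        np.array_equal(future["lat"], baseline["lat"])
        and np.array_equal(future["lon"], baseline["lon"])
    ):
        raise ValueError("future and baseline summaries are on different grids")
    delta = future - baseline
    delta.attrs["slice"] = f"{future.attrs.get('slice')} minus {baseline.attrs.get('slice')}"
    return delta
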