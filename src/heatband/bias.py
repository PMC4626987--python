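"""Mean-matching bias correction against a reference monthly climatology.

Model output carries systematic errors that distort threshold-exceedance
statistics. The correction compares the model's monthly climatology over a
baseline period (default 1961-1990) with a reference climatology on the same
grid, derives one correction per calendar month and cell — additive (shift)
for maximum temperature, multiplicative (scaling) for relative humidity —
and applies it to every day of the full record, not only the baseline.

Corrections are per calendar month; no smoothing across month boundaries is
applied, so corrected series may show small step changes at month edges.
After a multiplicative correction, relative humidity is clipped to [0, 100]
and the clipped fraction is logged as a QC metric. Wind is never corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .timeaxis import check_full_years, year_range

logger = logging.getLogger(__name__)

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"


@dataclass
class CorrectionField:
    """12 monthly correction layers for one variable.

    ``values`` has dims (month, lat, lon); additive corrections are in the
    variable's units, multiplicative ones are dimensionless factors. Cells
    where a factor is undefined (zero model climatology) are NaN.
    """

    variable: str
    mode: str
    values: xr.DataArray

    def __post_init__(self) -> None:
        if self.mode not in (ADDITIVE, MULTIPLICATIVE):
            raise ValueError(f"unknown correction mode {self.mode!r}")
        if self.values.sizes.get("month") != 12:
            raise ValueError("correction must have exactly 12 monthly layers")


def monthly_climatology(
    field: xr.DataArray, baseline: tuple[int, int]
) -> xr.DataArray:
    """Per-month, per-cell mean of daily values over the baseline years.

    Parameters
    ----------
    field
        Daily (time, lat, lon) field with ``year`` and ``month`` coordinates.
    baseline
        Inclusive (start, end) years of the averaging window.

    Returns
    -------
    (month, lat, lon) DataArray; raises if any baseline year is missing
    or incomplete.
    """
    years = year_range(*baseline)
    check_full_years(field, years)
    sub = field.where(
        (field["year"] >= baseline[0]) & (field["year"] <= baseline[1]), drop=True
    )
    # accumulate in float64 so correction round-trips are exact to ~1e-12
    clim = sub.astype(np.float64).groupby("month").mean("time")
    clim.attrs.update(field.attrs)
    clim.attrs["baseline"] = f"{baseline[0]}-{baseline[1]}"
    return clim


def regrid_to_reference(
    field: xr.DataArray, target_lat: np.ndarray, target_lon: np.ndarray
) -> xr.DataArray:
    """Bilinear interpolation of each layer onto the target lat/lon grid.

    Points outside the source hull become NaN. Raises if the grids are
    disjoint in either coordinate.
    """
    for name, src, tgt in (
        ("lat", field["lat"].values, np.asarray(target_lat)),
        ("lon", field["lon"].values, np.asarray(target_lon)),
    ):
        if tgt.max() < src.min() or tgt.min() > src.max():
            raise ValueError(f"source and target {name} ranges are disjoint")
    out = field.interp(lat=target_lat, lon=target_lon, method="linear")
    out.attrs.update(field.attrs)
    return out


def derive_correction(
    model_clim: xr.DataArray, ref_clim: xr.DataArray, mode: str, variable: str = ""
) -> CorrectionField:
    """Correction per month/cell: ref - model (additive) or ref / model.

    Multiplicative factors are NaN wherever the model climatology is zero.
    """
    if model_clim.sizes != ref_clim.sizes or not (
        np.array_equal(model_clim["lat"], ref_clim["lat"])
        and np.array_equal(model_clim["lon"], ref_clim["lon"])
    ):
        raise ValueError("model and reference climatologies are on different grids")
    if mode == ADDITIVE:
        vals = ref_clim - model_clim
    elif mode == MULTIPLICATIVE:
        vals = ref_clim / model_clim.where(model_clim != 0)
        n_bad = int(vals.isnull().sum())
        if n_bad:
            logger.warning(
                "multiplicative correction undefined at %d month-cells "
                "(zero model climatology)", n_bad,
            )
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    vals = vals.rename(variable or model_clim.name or "correction")
    return CorrectionField(variable=variable or str(model_clim.name), mode=mode,
                           values=vals)


def apply_correction(
    field: xr.DataArray,
    corr: CorrectionField,
    clip: tuple[float, float] | None = None,
) -> xr.DataArray:
    """Adjust each daily value by its calendar month's correction.

    The correction is applied to the entire record. ``clip`` bounds the
    result (used as (0, 100) for relative humidity); the fraction of clipped
    values is logged. Days whose month has a missing correction become NaN
    with a warning.
    """
    if not (
        np.array_equal(field["lat"], corr.values["lat"])
        and np.array_equal(field["lon"], corr.values["lon"])
    ):
        raise ValueError("field is not on the correction's grid")
    daily_corr = corr.values.sel(month=field["month"])
    n_missing = int(daily_corr.isnull().sum())
    if n_missing:
        logger.warning(
            "%s: %d day-cells set missing (no correction defined)",
            corr.variable, n_missing,
        )
    field64 = field.astype(np.float64)
    if corr.mode == ADDITIVE:
        out = field64 + daily_corr
    else:
        out = field64 * daily_corr
    if clip is not None:
        lo, hi = clip
        n_clip = int(((out < lo) | (out > hi)).sum())
        if n_clip:
            logger.info(
                "%s: clipped %d of %d values (%.3f%%) to [%g, %g]",
                corr.variable, n_clip, out.size, 100.0 * n_clip / out.size, lo, hi,
            )
        out = out.clip(lo, hi)
    out = out.drop_vars("month", errors="ignore").rename(field.name)
    # sel() promoted month to a (time,) coord copy; restore original coords
    out = out.assign_coords(month=field["month"])
    out.attrs.update(field.attrs)
    return out


def bias_correct_member(
    member: xr.Dataset,
    reference: xr.Dataset,
    baseline: tuple[int, int],
) -> xr.Dataset:
    """Full correction of one ensemble member.

    Regrids the member to the reference grid (identity when grids already
    match), derives additive tmax and multiplicative rh corrections from the
    baseline climatologies, and applies them across the whole record. Wind is
    passed through unchanged (regridded only).
    """
    ref_lat = reference["lat"].values
    ref_lon = reference["lon"].values
    same_grid = np.array_equal(member["lat"].values, ref_lat) and np.array_equal(
        member["lon"].values, ref_lon
    )

    def _regrid(da: xr.DataArray) -> xr.DataArray:
        return da if same_grid else regrid_to_reference(da, ref_lat, ref_lon)

    tmax = _regrid(member["tmax"])
    rh = _regrid(member["rh"])
    wind = _regrid(member["wind"])

    corr_t = derive_correction(
        monthly_climatology(tmax, baseline), reference["tmax"], ADDITIVE, "tmax"
    )
    corr_rh = derive_correction(
        monthly_climatology(rh, baseline), reference["rh"], MULTIPLICATIVE, "rh"
    )
    out = xr.Dataset(
        {
            "tmax": apply_correction(tmax, corr_t),
            "rh": apply_correction(rh, corr_rh, clip=(0.0, 100.0)),
            "wind": wind,
        }
    )
    out.attrs.update(member.attrs)
    return out
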