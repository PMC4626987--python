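"""Apparent temperature (AT), non-radiation Australian BoM formulation.

    AT = Ta + 0.33*e - 0.70*ws - 4.00

with Ta the dry-bulb temperature (degC), e the water vapour pressure (hPa)
and ws the 10 m wind speed (m/s). Vapour pressure is derived from relative
humidity via the Magnus saturation curve

    e_s(Ta) = 6.105 * exp(17.27*Ta / (237.7 + Ta))   [hPa]
    e = (rh / 100) * e_s(Ta)

the formulation published alongside the BoM index. The daily maximum AT is
formed from same-day daily maximum temperature, relative humidity and wind:
evaluating e at the daily maximum temperature maximizes AT for the given
daily fields. Negative AT values are retained. No radiation term, WBGT,
humidex or NWS heat-index variant is provided.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

# Magnus saturation-vapour-pressure constants (hPa, dimensionless, degC)
MAGNUS_A = 6.105
MAGNUS_B = 17.27
MAGNUS_C = 237.7

# AT linear coefficients: vapour pressure (degC/hPa), wind (degC per m/s), offset (degC)
AT_VAPOR_COEF = 0.33
AT_WIND_COEF = 0.70
AT_OFFSET = 4.00

_TA_RANGE = (-60.0, 60.0)


def saturation_vapor_pressure(ta):
    """Magnus saturation vapour pressure e_s(Ta) in hPa.

    Strictly increasing in Ta; valid for Ta in (-60, 60) degC. NaNs pass
    through (missing days stay missing).
    """
    arr = np.asarray(ta, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() <= _TA_RANGE[0] or finite.max() >= _TA_RANGE[1]):
        raise ValueError(f"temperature outside plausible range {_TA_RANGE} degC")
    es = MAGNUS_A * np.exp(MAGNUS_B * arr / (MAGNUS_C + arr))
    if isinstance(ta, xr.DataArray):
        out = ta.copy(data=es)
        out.attrs = {"units": "hPa"}
        return out
    return es if arr.ndim else float(es)


def vapor_pressure(ta, rh):
    """Water vapour pressure e = (rh/100) * e_s(Ta) in hPa; rh in [0, 100] %."""
    rh_arr = np.asarray(rh, dtype=float)
    finite = rh_arr[np.isfinite(rh_arr)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 100.0):
        raise ValueError("relative humidity outside [0, 100] %")
    return (rh / 100.0) * saturation_vapor_pressure(ta)


def apparent_temperature(ta, e, ws):
    """AT = Ta + 0.33*e - 0.70*ws - 4.00, all inputs element-wise."""
    ws_arr = np.asarray(ws, dtype=float)
    finite = ws_arr[np.isfinite(ws_arr)]
    if finite.size and finite.min() < 0.0:
        raise ValueError("wind speed must be non-negative")
    return ta + AT_VAPOR_COEF * e - AT_WIND_COEF * ws - AT_OFFSET


def daily_atmax(
    tmax: xr.DataArray, rh: xr.DataArray, wind: xr.DataArray
) -> xr.DataArray:
    """Daily maximum apparent temperature on (time, lat, lon).

    All three inputs must share identical time/lat/lon axes. Any missing
    input value yields a missing output value.
    """
    for other, name in ((rh, "rh"), (wind, "wind")):
        for dim in ("time", "lat", "lon"):
            if not np.array_equal(tmax[dim].values, other[dim].values):
                raise ValueError(f"{name}: {dim} axis does not match tmax")
    e = vapor_pressure(tmax, rh)
    at = apparent_temperature(tmax, e, wind)
    at = at.rename("atmax")
    at.attrs = {"units": "degC", "long_name": "daily maximum apparent temperature"}
    return at
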