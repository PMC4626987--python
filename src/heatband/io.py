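"""NetCDF I/O through xarray's scipy backend (NetCDF3 classic).

NetCDF3 has no int64, so integer variables and coordinates are downcast to
int32 on write. All gridded products round-trip through these two helpers so
the on-disk convention lives in one place.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

_ENGINE = "scipy"


def _netcdf3_safe(ds: xr.Dataset) -> xr.Dataset:
    ds = ds.copy()
    for name in list(ds.variables):
        v = ds[name]
        if v.dtype == np.int64:
            ds[name] = v.astype(np.int32)
        elif v.dtype == np.uint32 or v.dtype == np.uint64:
            ds[name] = v.astype(np.int32)
        elif v.dtype == bool:
            ds[name] = v.astype(np.int8)
    return ds


def write_netcdf(obj: xr.Dataset | xr.DataArray, path: str | Path) -> Path:
    path = Path(path)
    ds = obj.to_dataset() if isinstance(obj, xr.DataArray) else obj
    path.parent.mkdir(parents=True, exist_ok=True)
    _netcdf3_safe(ds).to_netcdf(path, engine=_ENGINE)
    return path


def read_netcdf(path: str | Path) -> xr.Dataset:
    # load eagerly so the file handle is released immediately
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return ds.load()
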