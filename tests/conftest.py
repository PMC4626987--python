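import numpy as np
import pytest

from heatband.synth import SynthConfig
from heatband.timeaxis import make_daily_field


@pytest.fixture
def tiny_config():
    """Small deterministic generator config: 2 members, 15 years, 3x3 grid."""
    return SynthConfig(
        n_members=2, year_start=1961, year_end=1975, n_lat=3, n_lon=3,
        lat_start=-10.0, lon_start=20.0, dlat=10.0, dlon=10.0,
        noise_sd_t=0.0, noise_sd_rh=0.0, wind_sd=0.0,
        trend_degC_per_century=0.0, bias_t=0.0, bias_rh=1.0, seed=7,
    )


@pytest.fixture
def constant_field():
    """Factory for a spatially/temporally constant daily field."""

    def make(value=20.0, name="tmax", years=(1961, 1962), n_lat=2, n_lon=2):
        y0, y1 = years
        n = (y1 - y0 + 1) * 365
        data = np.full((n, n_lat, n_lon), float(value), dtype=np.float64)
        return make_daily_field(
            data, name, "degC",
            lat=np.arange(n_lat, dtype=float), lon=np.arange(n_lon, dtype=float),
            year_start=y0, year_end=y1,
        )

    return make
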