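import numpy as np
import pandas as pd
import pytest
import xarray as xr

from aqhia.grids import GridSpec


@pytest.fixture
def small_grid():
    return GridSpec(n_lat=4, n_lon=5, lat0=30.0, lon0=-100.0, dlat=1.0, dlon=1.0)


def hourly_field(values, start="2020-04-01", **attrs):
    """Wrap a (t, nlat, nlon) array as an hourly ozone field."""
    values = np.asarray(values, dtype=float)
    base = {"pollutant": "O3", "units": "ppb", "cadence": "hourly"}
    base.update(attrs)
    return xr.DataArray(
        values,
        coords={
            "time": pd.date_range(start, periods=values.shape[0], freq="h"),
            "lat": np.arange(values.shape[1], dtype=float),
            "lon": np.arange(values.shape[2], dtype=float),
        },
        dims=("time", "lat", "lon"),
        attrs=base,
    )


def daily_field(values, start="2020-04-01", **attrs):
    values = np.asarray(values, dtype=float)
    base = {"pollutant": "O3", "units": "ppb", "cadence": "daily"}
    base.update(attrs)
    return xr.DataArray(
        values,
        coords={
            "time": pd.date_range(start, periods=values.shape[0], freq="D"),
            "lat": np.arange(values.shape[1], dtype=float),
            "lon": np.arange(values.shape[2], dtype=float),
        },
        dims=("time", "lat", "lon"),
        attrs=base,
    )


def surface(values, **attrs):
    values = np.asarray(values, dtype=float)
    return xr.DataArray(
        values,
        coords={"lat": np.arange(values.shape[0], dtype=float), "lon": np.arange(values.shape[1], dtype=float)},
        dims=("lat", "lon"),
        attrs=attrs,
    )


def mda8_brute_force(series, min_valid_hours=6, min_valid_windows=13):
    """Exhaustive 24-start-hour MDA8 for one hourly series (independent oracle)."""
    series = np.asarray(series, dtype=float)
    t = len(series)
    out = []
    for d in range(t // 24):
        means = []
        for h in range(24):
            s = d * 24 + h
            window = [series[s + k] for k in range(8) if s + k < t]
            vals = [v for v in window if np.isfinite(v)]
            if len(vals) >= min_valid_hours:
                means.append(sum(vals) / len(vals))
        out.append(max(means) if len(means) >= min_valid_windows else np.nan)
    return np.array(out)
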