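"""Exposure metrics, attribution, and ozone-regime diagnostics on gridded fields.

Concentration fields are ``xarray.DataArray`` objects with dims
``(time, lat, lon)`` and attributes ``pollutant``, ``units``, ``met_year``,
``scenario``, ``cadence``.  Exposure surfaces are ``(lat, lon)`` arrays with a
``metric`` attribute.

The MDA8 (daily maximum 8-hour average ozone) convention used throughout:

* candidate 8-h windows start at every local hour 0-23 and may extend into the
  next day;
* a window is valid if at least 6 of its 8 hourly values are present, its mean
  taken over the present values;
* a day is valid if at least 13 of its 24 windows are valid; otherwise the day
  is missing;
* MDA8 = maximum over the valid windows.

A newer convention restricts start hours to 7:00-23:00; it is available via
``start_hours``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "mda8_daily",
    "annual_nth_highest",
    "period_mean",
    "population_weighted",
    "attribute_change",
    "site_change_stats",
    "fnr",
    "classify_regime",
    "mda8_values",
]

#: labels for the photochemical ozone-production regimes
VOC_LIMITED = "VOC-limited"
TRANSITION = "transition"
NOX_LIMITED = "NOx-limited"


def mda8_values(
    hourly: np.ndarray,
    min_valid_hours: int = 6,
    min_valid_windows: int = 13,
    start_hours: tuple[int, int] = (0, 23),
) -> np.ndarray:
    """MDA8 of an hourly array along its first axis.

    ``hourly`` has shape (n_days * 24, ...); missing hours are NaN.  Returns an
    array of shape (n_days, ...) with NaN for invalid days.  Windows whose tail
    extends past the end of the record are evaluated on the hours that exist
    (subject to the ``min_valid_hours`` rule).
    """
    hourly = np.asarray(hourly, dtype=float)
    t = hourly.shape[0]
    if t % 24 != 0:
        raise ValueError("hourly record length must be a multiple of 24")
    n_days = t // 24
    valid = np.isfinite(hourly)
    filled = np.where(valid, hourly, 0.0)

    # 8-h sums by shifted adds in index order: bit-identical to summing the
    # present values one by one, so results match an explicit window scan
    # exactly (missing hours contribute an exact 0).  Windows truncate at the
    # end of the record (zero padding).
    pad = ((0, 7),) + ((0, 0),) * (hourly.ndim - 1)
    fpad = np.pad(filled, pad)
    vpad = np.pad(valid, pad)
    wsum = np.zeros_like(filled)
    wcnt = np.zeros(hourly.shape, dtype=np.int64)
    for k in range(8):
        wsum += fpad[k : k + t]
        wcnt += vpad[k : k + t]
    with np.errstate(invalid="ignore", divide="ignore"):
        wmean = np.where(wcnt >= min_valid_hours, wsum / np.maximum(wcnt, 1), np.nan)

    wmean = wmean.reshape((n_days, 24) + hourly.shape[1:])
    h0, h1 = start_hours
    wmean = wmean[:, h0 : h1 + 1]
    n_valid = np.isfinite(wmean).sum(axis=1)
    day_ok = n_valid >= min_valid_windows
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        best = np.nanmax(wmean, axis=1)
    return np.where(day_ok, best, np.nan)


def mda8_daily(hourly: xr.DataArray, start_hours: tuple[int, int] = (0, 23)) -> xr.DataArray:
    """Daily maximum 8-hour average ozone from an hourly field."""
    if hourly.attrs.get("pollutant", "O3") != "O3":
        raise ValueError("MDA8 is defined for O3 fields")
    if hourly.attrs.get("cadence", "hourly") != "hourly":
        raise ValueError("MDA8 requires hourly input")
    times = pd.DatetimeIndex(hourly["time"].values)
    if len(times) % 24 != 0 or not (times.hour[:24] == np.arange(24)).all():
        raise ValueError("time axis must consist of whole local days at hourly cadence")
    daily = mda8_values(hourly.values, start_hours=start_hours)
    days = times[::24].normalize()
    out = xr.DataArray(
        daily,
        coords={"time": days, "lat": hourly["lat"], "lon": hourly["lon"]},
        dims=("time", "lat", "lon"),
        attrs=dict(hourly.attrs),
    )
    out.attrs["cadence"] = "daily"
    out.attrs["metric"] = "MDA8"
    return out


def annual_nth_highest(daily: xr.DataArray, n: int = 4) -> xr.DataArray:
    """Per-cell n-th largest daily value (n=4 gives the ozone design metric)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    vals = daily.values
    n_valid = np.isfinite(vals).sum(axis=0)
    ranked = np.sort(np.where(np.isfinite(vals), vals, -np.inf), axis=0)
    if vals.shape[0] < n:
        result = np.full(vals.shape[1:], np.nan)
    else:
        result = ranked[-n]
    result = np.where(n_valid >= n, result, np.nan)
    if np.any(n_valid < n):
        warnings.warn(f"{int((n_valid < n).sum())} cell(s) have fewer than {n} valid days; set to missing")
    out = daily.isel(time=0, drop=True).copy(data=result)
    out.attrs["metric"] = f"{daily.attrs.get('metric', 'daily')}_{n}th_max"
    return out


def period_mean(field: xr.DataArray, window: tuple | None = None, min_coverage: float = 0.75) -> xr.DataArray:
    """Per-cell arithmetic mean over a time window; missing below ``min_coverage``."""
    sel = field if window is None else field.sel(time=slice(window[0], window[1]))
    if sel.sizes["time"] == 0:
        raise ValueError("empty averaging window")
    vals = sel.values
    n_valid = np.isfinite(vals).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
    mean = np.where(n_valid >= min_coverage * vals.shape[0], mean, np.nan)
    out = sel.isel(time=0, drop=True).copy(data=mean)
    out.attrs["metric"] = f"{field.attrs.get('metric', field.attrs.get('pollutant', 'field'))}_period_mean"
    return out


def population_weighted(
    surface: xr.DataArray,
    pop: xr.DataArray,
    mask: xr.DataArray | np.ndarray | None = None,
    sd_weights: str = "population",
) -> tuple[float, float]:
    """Population-weighted mean and SD of a surface.

    ``sd_weights="population"`` gives the population-weighted SD;
    ``"uniform"`` the plain cell SD over the same cells.
    """
    x = np.asarray(surface.values, dtype=float).ravel()
    p = np.asarray(pop.values, dtype=float).ravel()
    if x.shape != p.shape:
        raise ValueError("surface and population grids are not aligned")
    keep = np.isfinite(x) & (p > 0)
    if mask is not None:
        keep &= np.asarray(mask).ravel().astype(bool)
    ptot = p[keep].sum()
    if ptot <= 0:
        raise ValueError("zero total population under the mask")
    x, p = x[keep], p[keep]
    mean = float(np.sum(p * x) / ptot)
    if sd_weights == "population":
        sd = float(np.sqrt(np.sum(p * (x - mean) ** 2) / ptot))
    elif sd_weights == "uniform":
        sd = float(np.std(x))
    else:
        raise ValueError("sd_weights must be 'population' or 'uniform'")
    return mean, sd


def attribute_change(f_ab: xr.DataArray, f_bb: xr.DataArray, f_bc: xr.DataArray) -> dict[str, xr.DataArray]:
    """Split a scenario-pair change into meteorology and emission parts.

    Inputs are the same metric under (met A, BAU), (met B, BAU), (met B, COV).
    With the (met B, BAU) pivot the decomposition telescopes exactly:
    ``met_effect + emission_effect = total`` cell-wise.
    """

    def tag(f, key):
        return str(f.attrs.get(key, ""))

    if tag(f_ab, "scenario") != tag(f_bb, "scenario"):
        raise ValueError("f_AB and f_BB must share the emission scenario")
    if tag(f_ab, "met_year") == tag(f_bb, "met_year"):
        raise ValueError("f_AB and f_BB must differ in meteorology year")
    if tag(f_bb, "met_year") != tag(f_bc, "met_year"):
        raise ValueError("f_BB and f_BC must share the meteorology year")
    if tag(f_bb, "scenario") == tag(f_bc, "scenario"):
        raise ValueError("f_BB and f_BC must differ in emission scenario")
    for f in (f_bb, f_bc):
        if f.shape != f_ab.shape:
            raise ValueError("fields are not aligned")
    emission = f_bc - f_bb
    met = f_bb - f_ab
    total = f_bc - f_ab
    for da, name in ((emission, "emission_effect"), (met, "met_effect"), (total, "total")):
        da.attrs["effect"] = name
    return {"met_effect": met, "emission_effect": emission, "total": total}


def site_change_stats(
    surface_y1: xr.DataArray, surface_y2: xr.DataArray, sites: list[tuple[float, float]]
) -> tuple[float, float]:
    """Mean and SD across monitor sites of the year-2 minus year-1 change.

    Sites are sampled at the nearest cell center (a monitor sits inside one
    model cell).  SD is the sample SD across sites (0 for a single site).
    """
    if len(sites) == 0:
        raise ValueError("no sites given")
    lat = surface_y1["lat"].values
    lon = surface_y1["lon"].values
    hlat = (lat[1] - lat[0]) / 2 if len(lat) > 1 else 0.5
    hlon = (lon[1] - lon[0]) / 2 if len(lon) > 1 else 0.5
    deltas = []
    for slat, slon in sites:
        if not (lat[0] - hlat <= slat <= lat[-1] + hlat and lon[0] - hlon <= slon <= lon[-1] + hlon):
            raise ValueError(f"site ({slat}, {slon}) outside grid domain")
        i = int(np.argmin(np.abs(lat - slat)))
        j = int(np.argmin(np.abs(lon - slon)))
        deltas.append(float(surface_y2.values[i, j] - surface_y1.values[i, j]))
    deltas = np.asarray(deltas)
    sd = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0
    return float(np.mean(deltas)), sd


def fnr(
    hcho_col: xr.DataArray, no2_col: xr.DataArray, window: tuple | None = None
) -> xr.DataArray:
    """Formaldehyde-to-NO2 column ratio: ratio of the period means.

    The ratio of period-mean columns is not the mean of per-overpass ratios;
    the former is used here because it is what regime indicator thresholds are
    calibrated on.
    """
    hcho_mean = period_mean(hcho_col, window) if "time" in hcho_col.dims else hcho_col
    no2_mean = period_mean(no2_col, window) if "time" in no2_col.dims else no2_col
    no2_vals = no2_mean.values
    if not np.any(np.isfinite(no2_vals) & (no2_vals > 0)):
        raise ValueError("NO2 columns are zero or missing everywhere")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(no2_vals > 0, hcho_mean.values / no2_vals, np.nan)
    out = no2_mean.copy(data=ratio)
    out.attrs = {"metric": "FNR", "units": "1"}
    return out


def classify_regime(fnr_surface: xr.DataArray, low: float, high: float) -> xr.DataArray:
    """Label each cell's ozone-production regime from its FNR value.

    FNR < low: VOC-limited; low <= FNR <= high: transition (bounds inclusive);
    FNR > high: NOx-limited.  Missing FNR gives an empty label.
    """
    if low >= high:
        raise ValueError("regime bounds require low < high")
    v = fnr_surface.values
    labels = np.full(v.shape, "", dtype=object)
    ok = np.isfinite(v)
    labels[ok & (v < low)] = VOC_LIMITED
    labels[ok & (v >= low) & (v <= high)] = TRANSITION
    labels[ok & (v > high)] = NOX_LIMITED
    out = fnr_surface.copy(data=labels)
    out.attrs = {"metric": "ozone_regime", "bounds": (low, high)}
    return out
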