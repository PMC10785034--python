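"""Synthetic inputs for the whole analysis chain.

Everything the pipeline consumes — paired-scenario concentration fields,
population, county-blocked baseline mortality, sectoral inventories, monthly
activity series, monitor sites, and satellite retrieval scenes — is generated
here with controllable ground truth, so every downstream stage is testable
offline without a chemistry-model run or data download.

Scenario fields emulate the statistical structure of regional-model output:

* hourly ozone = background + seasonal sinusoid + diurnal sinusoid
  + spatial anthropogenic enhancement x (1 - monthly_reduction[month])
  + AR(1) meteorological noise, clipped at 0;
* daily PM2.5 = log-normal meteorological draw, with the anthropogenic share
  of the draw scaled by (1 - monthly_reduction[month]).

The random-stream split is the load-bearing design choice: meteorological
noise is seeded by (seed, met_year) only, and the emission term is a
deterministic function of the scenario.  Two scenarios sharing a seed and a
meteorology year therefore differ *exactly* by the emission term, which makes
the paired-run attribution decomposition exact, mirroring simulations driven
by the same meteorology.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage, signal, stats

from .grids import GridSpec
from .satellite import RetrievalPixel

__all__ = [
    "ScenarioConfig",
    "CovidSectorProfile",
    "DEFAULT_COVID_PROFILE",
    "DEFAULT_SECTORS",
    "generate_scenario_fields",
    "generate_population",
    "generate_mortality",
    "generate_activity",
    "generate_inventory",
    "generate_column_fields",
    "generate_sector_nox_fractions",
    "generate_sites",
    "generate_satellite_scene",
]

SCENARIOS = ("BAU", "COV", "REB")

#: month lengths of the (non-leap) analysis year
HOURS_PER_DAY = 24


def _rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic generator from a base seed plus stream labels."""
    entropy = [int(seed)]
    for lab in labels:
        h = hashlib.sha256(str(lab).encode()).digest()
        entropy.append(int.from_bytes(h[:4], "little"))
    return np.random.default_rng(entropy)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one (meteorology year, emission scenario) field set.

    ``monthly_reduction[m-1]`` is the fraction of the anthropogenic
    enhancement removed in calendar month ``m``; it must be all zero for BAU.
    Reductions apply multiplicatively to the anthropogenic enhancement only,
    never to the background.
    """

    met_year: str
    scenario: str
    o3_background: float = 30.0  # ppb
    o3_enhancement: float = 12.0  # ppb, spatial mean of the anthropogenic term
    enhancement_pattern: str = "urban"  # 'urban' (plume bumps) or 'uniform'
    diurnal_amplitude: float = 8.0  # ppb
    seasonal_amplitude: float = 10.0  # ppb
    ar1_rho: float = 0.6
    noise_sd: float = 5.0  # ppb, marginal SD of the AR(1) noise
    noise_spatial_corr: float = 0.0  # Gaussian smoothing length, cells (0 = iid)
    monthly_reduction: tuple = tuple([0.0] * 12)
    pm25_median: float = 7.0  # ug m-3
    pm25_gsd: float = 1.6
    pm25_anthro_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if len(self.monthly_reduction) != 12:
            raise ValueError("monthly_reduction must have 12 entries")
        if any(not 0 <= r <= 1 for r in self.monthly_reduction):
            raise ValueError("monthly reductions must lie in [0, 1]")
        if self.scenario == "BAU" and any(r != 0 for r in self.monthly_reduction):
            raise ValueError("BAU scenario must have zero monthly reductions")
        if min(self.diurnal_amplitude, self.seasonal_amplitude, self.noise_sd, self.o3_enhancement) < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("AR(1) rho must lie in [0, 1)")
        if self.pm25_gsd <= 1:
            raise ValueError("PM2.5 geometric SD must exceed 1")
        if not 0 <= self.pm25_anthro_fraction <= 1:
            raise ValueError("PM2.5 anthropogenic fraction must lie in [0, 1]")


def enhancement_field(grid: GridSpec, config: ScenarioConfig) -> np.ndarray:
    """Spatial anthropogenic enhancement, normalized to the configured mean.

    The 'urban' pattern is a sum of Gaussian plumes around centers drawn from
    the (seed, 'anthro') stream, shared by every scenario with the same seed so
    that paired scenarios see an identical emission footprint.
    """
    if config.enhancement_pattern == "uniform":
        return np.full(grid.shape, config.o3_enhancement)
    if config.enhancement_pattern != "urban":
        raise ValueError("enhancement_pattern must be 'urban' or 'uniform'")
    rng = _rng(config.seed, "anthro")
    n_bumps = 8
    lat = grid.lats[:, None]
    lon = grid.lons[None, :]
    clat = rng.uniform(grid.lats[0], grid.lats[-1], n_bumps)
    clon = rng.uniform(grid.lons[0], grid.lons[-1], n_bumps)
    width = rng.uniform(1.0, 3.0, n_bumps)  # degrees
    pattern = np.full(grid.shape, 0.15)
    for k in range(n_bumps):
        d2 = (lat - clat[k]) ** 2 + (lon - clon[k]) ** 2
        pattern += np.exp(-d2 / (2 * width[k] ** 2))
    pattern *= 1.0 / pattern.mean()
    return config.o3_enhancement * pattern


def _ar1_noise(shape: tuple, rho: float, sd: float, rng: np.random.Generator, spatial_corr: float) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    eps = rng.standard_normal(shape)
    if spatial_corr > 0:
        eps = ndimage.gaussian_filter(eps, sigma=(0, spatial_corr, spatial_corr))
        eps /= eps.std()
    innov_sd = sd * np.sqrt(1 - rho**2)
    eps *= innov_sd
    eps[0] *= sd / innov_sd  # stationary start
    return signal.lfilter([1.0], [1.0, -rho], eps, axis=0)


def _times(n_days: int, start: str) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_days * HOURS_PER_DAY, freq="h")


def generate_scenario_fields(
    grid: GridSpec,
    configs: list[ScenarioConfig],
    n_days: int = 365,
    start: str = "2020-04-01",
) -> dict[tuple[str, str], dict[str, xr.DataArray]]:
    """Hourly O3 and daily PM2.5 fields for each (met_year, scenario).

    Requires a BAU partner (same met_year) for every reduced-emission
    scenario, so the attribution pairs exist.  Identical config and seed give
    bit-identical fields.
    """
    met_by_scen = {(c.met_year, c.scenario) for c in configs}
    for c in configs:
        if c.scenario != "BAU" and (c.met_year, "BAU") not in met_by_scen:
            raise ValueError(f"scenario {c.scenario}/{c.met_year} has no BAU partner with the same meteorology")

    hours = None
    out: dict[tuple[str, str], dict[str, xr.DataArray]] = {}
    for c in configs:
        hours = _times(n_days, start)
        month_h = hours.month.to_numpy()
        doy = hours.dayofyear.to_numpy()
        hod = hours.hour.to_numpy()

        seasonal = c.seasonal_amplitude * np.cos(2 * np.pi * (doy - 196) / 365.0)
        diurnal = c.diurnal_amplitude * np.cos(2 * np.pi * (hod - 15) / 24.0)
        red = np.asarray(c.monthly_reduction)[month_h - 1]
        enh = enhancement_field(grid, c)

        noise = _ar1_noise(
            (len(hours),) + grid.shape, c.ar1_rho, c.noise_sd, _rng(c.seed, c.met_year, "o3"), c.noise_spatial_corr
        )
        o3 = (
            c.o3_background
            + seasonal[:, None, None]
            + diurnal[:, None, None]
            + enh[None] * (1.0 - red[:, None, None])
            + noise
        )
        np.clip(o3, 0.0, None, out=o3)
        o3_da = xr.DataArray(
            o3,
            coords={"time": hours, **grid.coords()},
            dims=("time", "lat", "lon"),
            attrs={
                "pollutant": "O3",
                "units": "ppb",
                "cadence": "hourly",
                "met_year": c.met_year,
                "scenario": c.scenario,
            },
        )

        days = hours[::HOURS_PER_DAY].normalize()
        month_d = days.month.to_numpy()
        red_d = np.asarray(c.monthly_reduction)[month_d - 1]
        lrng = _rng(c.seed, c.met_year, "pm25")
        met_pm = np.exp(lrng.normal(np.log(c.pm25_median), np.log(c.pm25_gsd), (len(days),) + grid.shape))
        pm = met_pm * (1.0 - c.pm25_anthro_fraction * red_d[:, None, None])
        pm_da = xr.DataArray(
            pm,
            coords={"time": days, **grid.coords()},
            dims=("time", "lat", "lon"),
            attrs={
                "pollutant": "PM25",
                "units": "ug m-3",
                "cadence": "daily",
                "met_year": c.met_year,
                "scenario": c.scenario,
            },
        )
        out[(c.met_year, c.scenario)] = {"o3": o3_da, "pm25": pm_da}
    return out


def generate_population(
    grid: GridSpec,
    n_centers: int = 12,
    seed: int = 0,
    decay: float = 0.15,  # per squared degree of distance from an urban center
    dispersion: float = 0.8,  # sigma of multiplicative log-normal heterogeneity
    total: float = 331e6,  # persons
) -> xr.DataArray:
    """Clustered log-normal population counts normalized to a national total."""
    if n_centers < 1:
        raise ValueError("need at least one population center")
    rng = _rng(seed, "population")
    lat = grid.lats[:, None]
    lon = grid.lons[None, :]
    clat = rng.uniform(grid.lats[0], grid.lats[-1], n_centers)
    clon = rng.uniform(grid.lons[0], grid.lons[-1], n_centers)
    density = np.zeros(grid.shape)
    for k in range(n_centers):
        d2 = (lat - clat[k]) ** 2 + (lon - clon[k]) ** 2
        density += np.exp(-decay * d2)
    if dispersion > 0:
        density *= np.exp(rng.normal(0.0, dispersion, grid.shape))
    density *= total / density.sum()
    return grid.surface(density, units="persons")


def generate_mortality(
    grid: GridSpec,
    n_counties: int = 24,
    mean_rate: float = 0.0087,  # deaths per person per year (US-like crude rate)
    sd_rate: float = 0.0015,
    seed: int = 0,
) -> xr.Dataset:
    """Baseline annual all-cause mortality rates on rectangular county blocks.

    ``n_counties`` is factored into an exact nr x nc rectangular tiling (the
    largest divisor at most sqrt(n_counties) sets nr), each county drawing one
    rate from Normal(mean_rate, sd_rate) truncated to (0, 1).
    """
    if not 0 < mean_rate < 1:
        raise ValueError("mean rate must lie in (0, 1)")
    if sd_rate < 0:
        raise ValueError("rate SD must be non-negative")
    nr = max(d for d in range(1, int(np.sqrt(n_counties)) + 1) if n_counties % d == 0)
    nc = n_counties // nr
    if nr > grid.n_lat or nc > grid.n_lon:
        raise ValueError("more counties than grid rows/columns allow")
    row_block = np.repeat(np.arange(nr), np.diff(np.linspace(0, grid.n_lat, nr + 1).astype(int)))
    col_block = np.repeat(np.arange(nc), np.diff(np.linspace(0, grid.n_lon, nc + 1).astype(int)))
    county_id = row_block[:, None] * nc + col_block[None, :]

    if sd_rate == 0:
        rates = np.full(n_counties, mean_rate)
    else:
        a, b = (0.0 - mean_rate) / sd_rate, (1.0 - mean_rate) / sd_rate
        rates = stats.truncnorm.rvs(a, b, loc=mean_rate, scale=sd_rate, size=n_counties, random_state=_rng(seed, "mortality"))
    values = rates[county_id]
    return xr.Dataset(
        {
            "rate": (("lat", "lon"), values, {"units": "yr-1"}),
            "county_id": (("lat", "lon"), county_id),
        },
        coords=grid.coords(),
    )


@dataclass(frozen=True)
class CovidSectorProfile:
    """Pandemic activity shape for one sector: trough depth, month, rebound."""

    depth: float  # fraction of activity lost at the trough, in [0, 1]
    trough_month: int  # sequential month number of the trough (4 = April)
    rebound: float  # per-month relaxation rate toward baseline (0 = no rebound)

    def __post_init__(self) -> None:
        if not 0 <= self.depth <= 1:
            raise ValueError("trough depth must lie in [0, 1]")
        if self.rebound < 0:
            raise ValueError("rebound rate must be non-negative")


#: pandemic-year activity profiles; gasoline's 40% April trough anchors the set
DEFAULT_COVID_PROFILE: dict[str, CovidSectorProfile] = {
    "onroad_gasoline": CovidSectorProfile(0.40, 4, 0.35),
    "onroad_diesel": CovidSectorProfile(0.20, 4, 0.30),
    "nonroad": CovidSectorProfile(0.30, 4, 0.25),
    "point": CovidSectorProfile(0.15, 4, 0.20),
    "og": CovidSectorProfile(0.20, 5, 0.12),
    "vcp": CovidSectorProfile(0.25, 4, 0.45),
}

DEFAULT_SECTORS = tuple(DEFAULT_COVID_PROFILE) + ("agriculture", "fugitive_dust")


def generate_activity(
    sectors: tuple[str, ...] | list[str],
    months: tuple[int, ...] | list[int] = tuple(range(1, 13)),
    covid_profile: dict[str, CovidSectorProfile] | None = None,
    seed: int | None = None,
    jitter: float = 0.0,
) -> pd.DataFrame:
    """Monthly activity scalings per sector relative to the baseline year.

    Sectors without a profile stay at 1 (the BAU reference series).  With a
    profile, the series is 1 before the trough month and
    ``1 - depth * exp(-rebound * (m - trough))`` from the trough onward.
    ``months`` are sequential month numbers (13 = January of the next year),
    so multi-year series rebound continuously.  Optional log-normal jitter
    (SD ``jitter``) emulates reporting noise in the activity proxies.
    """
    profile = DEFAULT_COVID_PROFILE if covid_profile is None else covid_profile
    rng = _rng(seed, "activity") if (seed is not None and jitter > 0) else None
    rows = []
    for sector in sectors:
        p = profile.get(sector)
        for m in months:
            if p is None or m < p.trough_month:
                s = 1.0
            else:
                s = 1.0 - p.depth * np.exp(-p.rebound * (m - p.trough_month))
            if rng is not None:
                s *= float(np.exp(rng.normal(0.0, jitter)))
            rows.append({"sector": sector, "month": m, "scaling": s})
    return pd.DataFrame(rows)


#: rough share of each species' national emissions contributed by each sector
_SECTOR_SPECIES_SHARE = {
    "onroad_gasoline": {"CO": 0.35, "NOx": 0.20, "VOC": 0.15, "SO2": 0.01, "NH3": 0.08, "PM2.5": 0.03},
    "onroad_diesel": {"CO": 0.05, "NOx": 0.30, "VOC": 0.04, "SO2": 0.01, "NH3": 0.01, "PM2.5": 0.06},
    "nonroad": {"CO": 0.30, "NOx": 0.15, "VOC": 0.10, "SO2": 0.02, "NH3": 0.01, "PM2.5": 0.05},
    "point": {"CO": 0.10, "NOx": 0.25, "VOC": 0.08, "SO2": 0.85, "NH3": 0.05, "PM2.5": 0.25},
    "og": {"CO": 0.05, "NOx": 0.08, "VOC": 0.38, "SO2": 0.05, "NH3": 0.00, "PM2.5": 0.02},
    "vcp": {"CO": 0.00, "NOx": 0.00, "VOC": 0.23, "SO2": 0.00, "NH3": 0.00, "PM2.5": 0.01},
    "agriculture": {"CO": 0.05, "NOx": 0.01, "VOC": 0.01, "SO2": 0.01, "NH3": 0.80, "PM2.5": 0.18},
    "fugitive_dust": {"CO": 0.10, "NOx": 0.01, "VOC": 0.01, "SO2": 0.05, "NH3": 0.05, "PM2.5": 0.40},
}

#: national annual totals, t/yr, order-of-magnitude realism only
_SPECIES_TOTAL = {"CO": 6.0e7, "NOx": 1.0e7, "VOC": 1.6e7, "SO2": 1.8e6, "NH3": 4.0e6, "PM2.5": 5.5e6}


def generate_inventory(
    n_states: int = 10,
    sectors: tuple[str, ...] = DEFAULT_SECTORS,
    species: tuple[str, ...] = ("CO", "NOx", "VOC", "SO2", "NH3", "PM2.5"),
    months: tuple[int, ...] = tuple(range(1, 13)),
    seed: int = 0,
    base_year: str = "2019",
) -> pd.DataFrame:
    """Synthetic base-year sectoral inventory (species, sector, state, month).

    State sizes are log-normal (a few states dominate, as in real inventories)
    and monthly profiles carry mild seasonality.  Deterministic under seed.
    """
    rng = _rng(seed, "inventory", base_year)
    state_size = np.exp(rng.normal(0.0, 1.0, n_states))
    state_size /= state_size.sum()
    month_arr = np.asarray(months)
    seasonality = 1.0 + 0.15 * np.cos(2 * np.pi * (month_arr - 1) / 12.0)
    seasonality /= seasonality.mean()
    rows = []
    for sp in species:
        for sec in sectors:
            share = _SECTOR_SPECIES_SHARE.get(sec, {}).get(sp, 0.02)
            if share == 0:
                continue
            sector_state = state_size * np.exp(rng.normal(0.0, 0.3, n_states))
            sector_state /= sector_state.sum()
            annual = _SPECIES_TOTAL[sp] * share
            for si in range(n_states):
                for mi, m in enumerate(month_arr):
                    rows.append(
                        {
                            "species": sp,
                            "sector": sec,
                            "state": f"S{si:02d}",
                            "month": int(m),
                            "value": float(annual * sector_state[si] * seasonality[mi] / 12.0),
                        }
                    )
    return pd.DataFrame(rows)


def generate_column_fields(
    grid: GridSpec,
    config: ScenarioConfig,
    n_overpasses: int = 91,
    start: str = "2020-04-01",
    no2_background: float = 8e14,
    no2_enhancement: float = 6e15,
    hcho_background: float = 4e15,
    hcho_enhancement: float = 8e15,
    hcho_reduction_factor: float = 0.4,
    column_gsd: float = 1.15,
) -> dict[str, xr.DataArray]:
    """Daily-overpass NO2 and HCHO tropospheric column fields (molec cm-2).

    NO2 columns respond fully to the monthly emission reduction; HCHO, largely
    secondary, responds with a damped factor, so the formaldehyde-to-NO2 ratio
    rises under reduced NOx, as regime indicators expect.  Meteorological
    (log-normal) noise is seeded by (seed, met_year) only, so paired scenarios
    share it.
    """
    days = pd.date_range(start, periods=n_overpasses, freq="D")
    red = np.asarray(config.monthly_reduction)[days.month.to_numpy() - 1]
    pattern = enhancement_field(grid, config) / max(config.o3_enhancement, 1e-30)
    hcho_pattern = 0.4 + 0.6 * pattern  # more diffuse: secondary production

    out = {}
    for name, background, enhancement, factor, pat in (
        ("NO2_col", no2_background, no2_enhancement, 1.0, pattern),
        ("HCHO_col", hcho_background, hcho_enhancement, hcho_reduction_factor, hcho_pattern),
    ):
        rng = _rng(config.seed, config.met_year, name)
        noise = np.exp(rng.normal(0.0, np.log(column_gsd), (len(days),) + grid.shape))
        vals = (background + enhancement * pat[None] * (1.0 - factor * red[:, None, None])) * noise
        out[name] = xr.DataArray(
            vals,
            coords={"time": days, **grid.coords()},
            dims=("time", "lat", "lon"),
            attrs={
                "pollutant": name,
                "units": "molecules cm-2",
                "cadence": "daily",
                "met_year": config.met_year,
                "scenario": config.scenario,
            },
        )
    return out


def generate_sector_nox_fractions(grid: GridSpec, seed: int = 0) -> xr.Dataset:
    """Per-cell mobile/point/O&G shares of NOx emissions (sum <= 1).

    Each sector concentrates around its own centers, so parts of the domain
    clear the 60% dominance threshold for each label while rural cells stay
    'other'.
    """
    rng = _rng(seed, "nox-sectors")
    lat = grid.lats[:, None]
    lon = grid.lons[None, :]
    lon_span = grid.lons[-1] - grid.lons[0] if grid.n_lon > 1 else 1.0
    weights = {}
    # each sector draws its centers from its own longitude band so that every
    # label keeps dominant cells even on small domains
    bands = {"mobile": (0.0, 0.4), "point": (0.4, 0.7), "og": (0.7, 1.0)}
    for sector, n_centers, width in (("mobile", 6, 1.6), ("point", 5, 1.1), ("og", 3, 2.2)):
        b0, b1 = bands[sector]
        clat = rng.uniform(grid.lats[0], grid.lats[-1], n_centers)
        clon = rng.uniform(grid.lons[0] + b0 * lon_span, grid.lons[0] + b1 * lon_span, n_centers)
        w = np.zeros(grid.shape)
        for k in range(n_centers):
            d2 = (lat - clat[k]) ** 2 + (lon - clon[k]) ** 2
            w += np.exp(-d2 / (2 * width**2))
        weights[sector] = 4.0 * w
    floor = 0.6  # diffuse area sources everywhere
    total = floor + sum(weights.values())
    data = {k: (("lat", "lon"), w / total) for k, w in weights.items()}
    return xr.Dataset(data, coords=grid.coords())


def generate_sites(grid: GridSpec, n_sites: int = 40, seed: int = 0) -> pd.DataFrame:
    """Monitor-site table (site_id, lat, lon), sites inside the grid footprint."""
    rng = _rng(seed, "sites")
    lats = rng.uniform(grid.lats[0], grid.lats[-1], n_sites)
    lons = rng.uniform(grid.lons[0], grid.lons[-1], n_sites)
    return pd.DataFrame({"site_id": [f"A{k:03d}" for k in range(n_sites)], "lat": lats, "lon": lons})


def generate_satellite_scene(
    model_no2_field: xr.DataArray,
    grid: GridSpec,
    n_pixels: int,
    noise: float = 0.1,
    seed: int = 0,
    n_layers: int = 10,
    tropopause_layer: int = 7,
    apriori: str = "climatology",
    sw_surface: float = 0.3,
    sw_top: float = 1.2,
    sw_jitter: float = 0.15,
    model_scale_height: float = 2.5,
    apriori_scale_height: float = 3.5,
) -> list[RetrievalPixel]:
    """Synthetic retrieval pixels over a true model column surface.

    Each pixel sits in one grid cell; its stored vertical column is the true
    model column times ``1 + noise * N(0,1)``.  Scattering weights increase
    linearly from ``sw_surface`` to ``sw_top`` (per-pixel multiplicative
    jitter), and the stored original AMF is self-consistent with the a priori
    profile.  ``apriori='model'`` makes the a priori the (scaled) model
    profile itself, the noise-free self-consistency case.
    """
    if n_pixels < 1:
        raise ValueError("need at least one pixel")
    if model_no2_field.shape != grid.shape:
        raise ValueError("model column surface must be 2-D on the grid")
    rng = _rng(seed, "satellite")
    vcd_true = np.asarray(model_no2_field.values, dtype=float)
    ii = rng.integers(0, grid.n_lat, n_pixels)
    jj = rng.integers(0, grid.n_lon, n_pixels)
    lats = grid.lats[ii] + rng.uniform(-0.4, 0.4, n_pixels) * grid.dlat
    lons = grid.lons[jj] + rng.uniform(-0.4, 0.4, n_pixels) * grid.dlon

    layers = np.arange(n_layers)
    model_shape = np.exp(-layers / model_scale_height)
    model_shape_trop = model_shape[: tropopause_layer + 1] / model_shape[: tropopause_layer + 1].sum()
    ap_scale = model_scale_height if apriori == "model" else apriori_scale_height
    ap_shape = np.exp(-layers / ap_scale)
    ap_shape_trop = ap_shape[: tropopause_layer + 1] / ap_shape[: tropopause_layer + 1].sum()
    sw_base = sw_surface + (sw_top - sw_surface) * layers / (n_layers - 1) if n_layers > 1 else np.full(1, sw_surface)

    qa = np.where(rng.uniform(size=n_pixels) < 0.85, rng.uniform(0.8, 1.0, n_pixels), rng.uniform(0.0, 0.7, n_pixels))
    cf = rng.beta(1.2, 5.0, n_pixels)
    sza = rng.uniform(15.0, 78.0, n_pixels)
    eps = rng.standard_normal(n_pixels)
    alpha = 1.0 + sw_jitter * (rng.uniform(size=n_pixels) - 0.5) * 2 if sw_jitter > 0 else np.ones(n_pixels)
    ap_col_factor = (
        np.ones(n_pixels) if apriori == "model" else np.exp(rng.normal(0.0, 0.15, n_pixels))
    )

    pixels = []
    for k in range(n_pixels):
        true_col = vcd_true[ii[k], jj[k]]
        ap = np.zeros(n_layers)
        ap[: tropopause_layer + 1] = true_col * ap_col_factor[k] * ap_shape_trop
        if n_layers > tropopause_layer + 1:
            # small stratospheric residual, outside the tropospheric AMF sums
            ap[tropopause_layer + 1 :] = 0.03 * true_col / (n_layers - tropopause_layer - 1)
        sw = alpha[k] * sw_base
        trop = slice(0, tropopause_layer + 1)
        amf_orig = float(np.dot(sw[trop], ap[trop]) / ap[trop].sum())
        pixels.append(
            RetrievalPixel(
                lat=float(lats[k]),
                lon=float(lons[k]),
                vcd=float(true_col * (1.0 + noise * eps[k])),
                amf_orig=amf_orig,
                scattering_weights=sw,
                apriori=ap,
                tropopause_layer=tropopause_layer,
                qa=float(qa[k]),
                cloud_fraction=float(cf[k]),
                sza=float(sza[k]),
            )
        )
    return pixels
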