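"""End-to-end driver: inventories -> scenarios -> exposure -> health -> satellite.

``run_pipeline`` chains the whole assessment on synthetic inputs with fixed
seeds and returns (and optionally writes) a machine-readable summary:

1. a synthetic base-year inventory is scaled by pandemic activity series; the
   national monthly fractional change of the gas-phase precursors (CO, NOx,
   VOC, SO2) becomes the monthly reduction applied to the scenario fields'
   anthropogenic enhancement — the emissions accounting drives the
   concentration scenarios;
2. paired concentration fields (met A/BAU, met B/BAU, met B/COV) are reduced
   to annual exposure surfaces (4th-highest MDA8, annual-mean MDA8, annual
   PM2.5) and the change is attributed to emissions vs. meteorology;
3. attributable-mortality totals with RR-endpoint CIs, and the averted-deaths
   delta between scenarios;
4. a satellite-style column comparison over source regions with
   model-consistent AMFs and orthogonal-distance-regression slopes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .grids import GridSpec
from . import emissions, exposure, hia, satellite, synth
from .io import config_hash, save_config, write_netcdf, write_table

__all__ = ["RunConfig", "run_pipeline", "default_config"]

PRECURSORS = ("CO", "NOx", "VOC", "SO2")
STUDY_MONTHS = tuple(range(4, 16))  # April (4) .. March of next year (15)


@dataclass
class RunConfig:
    """All knobs of one reproducible pipeline run."""

    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    met_years: tuple[str, str] = ("2019", "2020")
    n_days: int = 365
    start: str = "2020-04-01"
    # synthetic-input sizes
    n_states: int = 10
    n_counties: int = 24
    n_pop_centers: int = 12
    population_total: float = 331e6
    mean_mortality_rate: float = 0.0087
    sd_mortality_rate: float = 0.0015
    # scenario field parameters (see synth.ScenarioConfig)
    o3_background: float = 30.0
    o3_enhancement: float = 12.0
    enhancement_pattern: str = "urban"
    diurnal_amplitude: float = 8.0
    seasonal_amplitude: float = 10.0
    ar1_rho: float = 0.6
    noise_sd: float = 5.0
    pm25_median: float = 7.0
    pm25_gsd: float = 1.6
    pm25_anthro_fraction: float = 0.5
    # satellite comparison
    n_pixels: int = 4000
    pixel_noise: float = 0.08
    qa_min: float = 0.75
    cf_max: float = 0.3
    sza_max: float = 70.0
    fnr_bounds: tuple[float, float] = (3.0, 4.5)
    n_sites: int = 40
    output_dir: str | None = None

    def scenario(self, met_year: str, scenario: str, monthly_reduction=None) -> synth.ScenarioConfig:
        return synth.ScenarioConfig(
            met_year=met_year,
            scenario=scenario,
            o3_background=self.o3_background,
            o3_enhancement=self.o3_enhancement,
            enhancement_pattern=self.enhancement_pattern,
            diurnal_amplitude=self.diurnal_amplitude,
            seasonal_amplitude=self.seasonal_amplitude,
            ar1_rho=self.ar1_rho,
            noise_sd=self.noise_sd,
            monthly_reduction=tuple(monthly_reduction) if monthly_reduction is not None else tuple([0.0] * 12),
            pm25_median=self.pm25_median,
            pm25_gsd=self.pm25_gsd,
            pm25_anthro_fraction=self.pm25_anthro_fraction,
            seed=self.seed,
        )


def default_config(seed: int = 0, **overrides) -> RunConfig:
    return replace(RunConfig(seed=seed), **overrides)


def _study_month_to_calendar(m: int) -> int:
    return ((m - 1) % 12) + 1


def scaled_study_inventories(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Base and scaled inventories over the study year, plus the activity table.

    The base inventory's calendar months are relabelled to sequential study
    months (4..15 = April through the following March), then scaled with the
    pandemic activity series.
    """
    base_cal = synth.generate_inventory(n_states=cfg.n_states, seed=cfg.seed)
    frames = []
    for m in STUDY_MONTHS:
        cal = _study_month_to_calendar(m)
        block = base_cal[base_cal["month"] == cal].copy()
        block["month"] = m
        frames.append(block)
    base = pd.concat(frames, ignore_index=True)
    activity = synth.generate_activity(synth.DEFAULT_COVID_PROFILE.keys(), months=STUDY_MONTHS)
    scaled = emissions.apply_monthly_scaling(base, activity)
    return base, scaled, activity


def reduction_vector(change: emissions.ChangeTable) -> np.ndarray:
    """Calendar-month reduction of the anthropogenic enhancement.

    The reduction is minus the national fractional change, averaged over the
    gas-phase precursor species, clipped to [0, 1].
    """
    red = np.zeros(12)
    nat = change.national
    for m in STUDY_MONTHS:
        rows = nat[(nat["month"] == m) & (nat["species"].isin(PRECURSORS))]
        red[_study_month_to_calendar(m) - 1] = np.clip(-rows["fraction"].mean(), 0.0, 1.0)
    return red


def _model_profile(column: float, n_layers: int = 10, tropopause_layer: int = 7, scale_height: float = 2.5) -> np.ndarray:
    layers = np.arange(n_layers)
    shape = np.exp(-layers / scale_height)
    prof = np.zeros(n_layers)
    trop = shape[: tropopause_layer + 1]
    prof[: tropopause_layer + 1] = column * trop / trop.sum()
    return prof


def _bin_pixels(pixels, adjusted, grid: GridSpec) -> xr.DataArray:
    """Cell-mean adjusted column from pixel samples (NaN where no pixel)."""
    sums = np.zeros(grid.shape)
    counts = np.zeros(grid.shape)
    for p, v in zip(pixels, adjusted):
        i, j = grid.nearest_cell(p.lat, p.lon)
        sums[i, j] += v
        counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return grid.surface(mean, units="molecules cm-2")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full chain; returns a nested summary dict (JSON-serializable).

    With ``cfg.output_dir`` set, also writes the exposure/deaths surfaces
    (NetCDF), the inventory change tables (CSV), a summary.json and a run log
    carrying the config hash, seed and package version.
    """
    grid = cfg.grid
    met_a, met_b = cfg.met_years

    # --- emissions accounting drives the scenario reductions
    base, scaled, activity = scaled_study_inventories(cfg)
    change = emissions.fractional_change(scaled, base, reference_year="baseline")
    red = reduction_vector(change)
    nox_aprjun = emissions.period_mean_change(change, "NOx", [4, 5, 6])
    voc_aprjun = emissions.period_mean_change(change, "VOC", [4, 5, 6])
    annual = {
        sp: emissions.period_mean_change(change, sp, list(STUDY_MONTHS)) for sp in emissions.SPECIES
    }

    # --- paired scenario fields
    configs = [
        cfg.scenario(met_a, "BAU"),
        cfg.scenario(met_b, "BAU"),
        cfg.scenario(met_b, "COV", monthly_reduction=red),
    ]
    fields = synth.generate_scenario_fields(grid, configs, n_days=cfg.n_days, start=cfg.start)

    pop = synth.generate_population(
        grid, n_centers=cfg.n_pop_centers, seed=cfg.seed, total=cfg.population_total
    )
    mort = synth.generate_mortality(
        grid, n_counties=cfg.n_counties, mean_rate=cfg.mean_mortality_rate,
        sd_rate=cfg.sd_mortality_rate, seed=cfg.seed,
    )

    # --- exposure surfaces
    surfaces: dict[tuple[str, str], dict[str, xr.DataArray]] = {}
    for key, f in fields.items():
        mda8 = exposure.mda8_daily(f["o3"])
        surfaces[key] = {
            "mda8_4th": exposure.annual_nth_highest(mda8, 4),
            "mda8_mean": exposure.period_mean(mda8),
            "pm25_mean": exposure.period_mean(f["pm25"]),
        }
        for s in surfaces[key].values():
            s.attrs.update({"met_year": key[0], "scenario": key[1]})
        surfaces[key]["mda8_4th"].attrs["units"] = "ppb"
        surfaces[key]["mda8_mean"].attrs["units"] = "ppb"
        surfaces[key]["pm25_mean"].attrs["units"] = "ug m-3"

    attribution = {}
    pw = {}
    for metric in ("mda8_4th", "mda8_mean", "pm25_mean"):
        parts = exposure.attribute_change(
            surfaces[(met_a, "BAU")][metric],
            surfaces[(met_b, "BAU")][metric],
            surfaces[(met_b, "COV")][metric],
        )
        attribution[metric] = parts
        pw[metric] = {
            name: exposure.population_weighted(part, pop) for name, part in parts.items()
        }

    sites = synth.generate_sites(grid, n_sites=cfg.n_sites, seed=cfg.seed)
    site_stats = exposure.site_change_stats(
        surfaces[(met_a, "BAU")]["mda8_4th"],
        surfaces[(met_b, "COV")]["mda8_4th"],
        list(zip(sites["lat"], sites["lon"])),
    )

    # --- health impact assessment (annual-mean MDA8 for O3, annual PM2.5)
    health = {}
    deaths_surfaces = {}
    for pollutant, metric, rr in (("O3", "mda8_mean", hia.RR_O3), ("PM25", "pm25_mean", hia.RR_PM25)):
        per_scenario = {}
        for scen in ("BAU", "COV"):
            dx = hia.excess_exposure(surfaces[(met_b, scen)][metric], rr)
            deaths = hia.attributable_deaths(pop, mort["rate"], hia.beta_from_rr(rr), dx)
            summary = hia.summarize(dx, pop, mort["rate"], rr)
            per_scenario[scen] = {"deaths": deaths, "summary": summary}
            deaths_surfaces[(pollutant, scen)] = deaths
        surface, averted_total, averted_pct = hia.averted(
            per_scenario["BAU"]["deaths"], per_scenario["COV"]["deaths"]
        )
        deaths_surfaces[(pollutant, "averted")] = surface.to_dataset(name="deaths")
        health[pollutant] = {
            "bau": per_scenario["BAU"]["summary"],
            "cov": per_scenario["COV"]["summary"],
            "averted_total": averted_total,
            "averted_percent": averted_pct,
        }

    # --- satellite-style column comparison (met B, BAU vs COV)
    col_bau = synth.generate_column_fields(grid, configs[1], start=cfg.start)
    col_cov = synth.generate_column_fields(grid, configs[2], start=cfg.start)
    no2_bau = exposure.period_mean(col_bau["NO2_col"])
    no2_cov = exposure.period_mean(col_cov["NO2_col"])
    fractions = synth.generate_sector_nox_fractions(grid, seed=cfg.seed)
    labels = satellite.classify_source_region(fractions)

    sat = {"regions": {}}
    pixel_surfaces = {}
    for scen, no2_mean in (("BAU", no2_bau), ("COV", no2_cov)):
        pixels = synth.generate_satellite_scene(
            no2_mean, grid, n_pixels=cfg.n_pixels, noise=cfg.pixel_noise, seed=cfg.seed
        )
        kept = satellite.filter_pixels(pixels, cfg.qa_min, cfg.cf_max, cfg.sza_max)
        adjusted = []
        for p in kept:
            i, j = grid.nearest_cell(p.lat, p.lon)
            prof = _model_profile(float(no2_mean.values[i, j]), p.n_layers, p.tropopause_layer)
            adjusted.append(satellite.recompute_amf(p, prof))
        pixel_surfaces[scen] = _bin_pixels(kept, adjusted, grid)
        sat.setdefault("pixels_kept", {})[scen] = len(kept)
        sat.setdefault("pixels_total", {})[scen] = len(pixels)

    for region in ("urban", "point", "oil_and_gas"):
        try:
            model_chg = satellite.regional_change(no2_bau, no2_cov, labels, region)
        except ValueError:
            model_chg = float("nan")
        try:
            sat_chg = satellite.regional_change(pixel_surfaces["BAU"], pixel_surfaces["COV"], labels, region)
        except ValueError:
            sat_chg = float("nan")
        sel = np.asarray(labels.values) == region
        x = no2_bau.values[sel]
        y = no2_cov.values[sel]
        keep = np.isfinite(x) & np.isfinite(y)
        fit = satellite.odr_fit(x[keep], y[keep]) if keep.sum() >= 3 else None
        sat["regions"][region] = {
            "n_cells": int(sel.sum()),
            "model_change": model_chg,
            "satellite_change": sat_chg,
            "odr_slope": None if fit is None else fit.slope,
            "odr_slope_ci95": None if fit is None else list(fit.slope_ci95),
        }

    # ozone-regime shift from the formaldehyde-to-NO2 ratio
    fnr_bau = exposure.fnr(col_bau["HCHO_col"], col_bau["NO2_col"])
    fnr_cov = exposure.fnr(col_cov["HCHO_col"], col_cov["NO2_col"])
    urban = np.asarray(labels.values) == "urban"
    fnr_change_pct = float(
        (fnr_cov.values[urban].mean() - fnr_bau.values[urban].mean()) / fnr_bau.values[urban].mean() * 100
    )
    regimes_cov = exposure.classify_regime(fnr_cov, *cfg.fnr_bounds)
    regime_counts = {
        lab: int((np.asarray(regimes_cov.values)[urban] == lab).sum())
        for lab in (exposure.VOC_LIMITED, exposure.TRANSITION, exposure.NOX_LIMITED)
    }

    summary = {
        "emissions": {
            "nox_apr_jun": {"mean": nox_aprjun[0], "sd": nox_aprjun[1]},
            "voc_apr_jun": {"mean": voc_aprjun[0], "sd": voc_aprjun[1]},
            "annual": {sp: {"mean": v[0], "sd": v[1]} for sp, v in annual.items()},
            "monthly_reduction": red.tolist(),
        },
        "exposure": {
            "population_weighted": {
                metric: {name: {"mean": v[0], "sd": v[1]} for name, v in parts.items()}
                for metric, parts in pw.items()
            },
            "site_change": {"mean": site_stats[0], "sd": site_stats[1]},
        },
        "health": {
            pol: {
                "bau_total": h["bau"].total,
                "bau_ci": [h["bau"].ci_low, h["bau"].ci_high],
                "cov_total": h["cov"].total,
                "cov_ci": [h["cov"].ci_low, h["cov"].ci_high],
                "averted_total": h["averted_total"],
                "averted_percent": h["averted_percent"],
            }
            for pol, h in health.items()
        },
        "satellite": sat,
        "fnr": {"urban_change_percent": fnr_change_pct, "urban_regime_counts_cov": regime_counts},
    }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(change.national.assign(kind="national"), out / "change_national.csv")
        write_table(change.by_sector, out / "change_by_sector.csv")
        write_table(change.by_state, out / "change_by_state.csv")
        write_table(activity, out / "activity.csv")
        for (met, scen), surfs in surfaces.items():
            for name, s in surfs.items():
                write_netcdf(s, out / f"{name}_{met}_{scen}.nc", name=name)
        for (pol, scen), ds in deaths_surfaces.items():
            write_netcdf(ds, out / f"deaths_{pol}_{scen}.nc")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        cfg_dict = asdict(cfg)
        cfg_dict["grid"] = asdict(cfg.grid)
        save_config(cfg_dict, out / "config.yaml")
        log = {
            "config_hash": config_hash(cfg_dict),
            "seed": cfg.seed,
            "version": __version__,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))

    summary["_surfaces"] = surfaces
    summary["_attribution"] = attribution
    summary["_deaths"] = deaths_surfaces
    summary["_pop"] = pop
    summary["_mort"] = mort
    return summary
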