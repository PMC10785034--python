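"""Log-linear attributable-mortality health impact assessment.

The model attributes a share of baseline all-cause mortality to long-term
pollutant exposure above a no-excess-risk threshold (TMREL):

    deaths = P * BR * (1 - exp(-beta * dX)),      beta = ln(RR) / increment

where P is population, BR the baseline annual all-cause mortality rate, dX the
exposure above the TMREL, and RR the relative risk per stated concentration
increment (e.g. 1.02 per 10 ppb annual-mean MDA8 ozone).  ``1 - exp(-beta*dX)``
is the attributable fraction; at dX equal to one increment it is exactly
``1 - 1/RR``.  Confidence intervals are propagated by re-running the chain at
the RR interval endpoints.

Default risk coefficients (all-cause mortality, long-term exposure):
ozone RR 1.02 (95% CI 1.01-1.04) per 10 ppb with TMREL 26.7 ppb; PM2.5 RR 1.06
(95% CI 1.04-1.08) per 10 ug m-3 with TMREL 2.8 ug m-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import xarray as xr

__all__ = [
    "RelativeRisk",
    "Beta",
    "RR_O3",
    "RR_PM25",
    "beta_from_rr",
    "excess_exposure",
    "attributable_deaths",
    "total_deaths",
    "summarize",
    "averted",
    "averted_percent",
    "HiaSummary",
]


@dataclass(frozen=True)
class RelativeRisk:
    """Relative risk with 95% CI, its exposure increment, and the TMREL."""

    rr: float
    ci_low: float
    ci_high: float
    increment: float
    tmrel: float
    pollutant: str
    units: str

    def __post_init__(self) -> None:
        if not (1.0 <= self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("require 1 <= ci_low <= rr <= ci_high")
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.tmrel < 0:
            raise ValueError("TMREL must be non-negative")


@dataclass(frozen=True)
class Beta:
    """Log-linear concentration-response slope, per exposure unit."""

    value: float


RR_O3 = RelativeRisk(rr=1.02, ci_low=1.01, ci_high=1.04, increment=10.0, tmrel=26.7, pollutant="O3", units="ppb")
RR_PM25 = RelativeRisk(
    rr=1.06, ci_low=1.04, ci_high=1.08, increment=10.0, tmrel=2.8, pollutant="PM25", units="ug m-3"
)


def beta_from_rr(rr: RelativeRisk, endpoint: str = "central") -> Beta:
    """beta = ln(RR)/increment, at the central RR or a CI endpoint."""
    value = {"central": rr.rr, "low": rr.ci_low, "high": rr.ci_high}[endpoint]
    if value <= 0:
        raise ValueError("relative risk must be positive")
    return Beta(math.log(value) / rr.increment)


def excess_exposure(metric: xr.DataArray, rr: RelativeRisk) -> xr.DataArray:
    """Exposure above the TMREL: dX = max(0, X - tmrel), cell-wise."""
    units = metric.attrs.get("units")
    if units is not None and units != rr.units:
        raise ValueError(f"metric units {units!r} do not match RR units {rr.units!r}")
    dx = xr.apply_ufunc(lambda x: np.maximum(0.0, x - rr.tmrel), metric, keep_attrs=True)
    dx.attrs["metric"] = "excess_exposure"
    dx.attrs["tmrel"] = rr.tmrel
    return dx


def attributable_deaths(
    pop: xr.DataArray, mort: xr.DataArray, beta: Beta, dx: xr.DataArray
) -> xr.Dataset:
    """Cell-wise attributable deaths and rate per 100,000 people per year.

    Cells with zero population contribute zero deaths and are excluded from
    the rate surface.  Missing exposure gives missing deaths.
    """
    for other in (mort, dx):
        if other.shape != pop.shape:
            raise ValueError("population, mortality and exposure grids are not aligned")
    p = pop.values.astype(float)
    br = mort.values.astype(float)
    d = dx.values.astype(float)
    if np.nanmin(d) < 0:
        raise ValueError("excess exposure must be non-negative")
    deaths = p * br * (1.0 - np.exp(-beta.value * d))
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(p > 0, deaths / p * 1e5, np.nan)
    ds = xr.Dataset(
        {
            "deaths": (("lat", "lon"), deaths),
            "rate_per_1e5": (("lat", "lon"), rate),
        },
        coords={"lat": pop["lat"], "lon": pop["lon"]},
    )
    ds["deaths"].attrs["units"] = "deaths yr-1"
    ds["rate_per_1e5"].attrs["units"] = "deaths yr-1 per 1e5 persons"
    return ds


def total_deaths(deaths: xr.Dataset, mask: np.ndarray | None = None) -> float:
    """Sum of the deaths surface over a region mask."""
    d = deaths["deaths"].values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty region mask")
        d = np.where(mask, d, 0.0)
    return float(np.nansum(d))


@dataclass(frozen=True)
class HiaSummary:
    total: float
    ci_low: float
    ci_high: float


def summarize(
    dx: xr.DataArray,
    pop: xr.DataArray,
    mort: xr.DataArray,
    rr: RelativeRisk,
    mask: np.ndarray | None = None,
) -> HiaSummary:
    """National (or masked) total attributable deaths with its 95% CI.

    CI endpoints re-run the whole chain with the RR interval endpoints, the
    same style in which epidemiological totals are usually quoted.
    """
    totals = {
        ep: total_deaths(attributable_deaths(pop, mort, beta_from_rr(rr, ep), dx), mask)
        for ep in ("central", "low", "high")
    }
    return HiaSummary(total=totals["central"], ci_low=totals["low"], ci_high=totals["high"])


def averted(deaths_bau: xr.Dataset, deaths_cov: xr.Dataset) -> tuple[xr.DataArray, float, int]:
    """Deaths averted by the reduced-emission scenario.

    Returns the cell-wise BAU-minus-COV surface, its total, and the total as a
    percent of the BAU total rounded to the nearest integer (the form in which
    such benefits are typically reported).
    """
    if deaths_bau["deaths"].shape != deaths_cov["deaths"].shape:
        raise ValueError("deaths surfaces are not aligned")
    surface = deaths_bau["deaths"] - deaths_cov["deaths"]
    total = float(np.nansum(surface.values))
    bau_total = float(np.nansum(deaths_bau["deaths"].values))
    percent = int(round(100.0 * total / bau_total)) if bau_total > 0 else 0
    return surface, total, percent


def averted_percent(total_bau: float, total_averted: float) -> int:
    """Averted deaths as an integer percent of the scenario total."""
    if total_bau <= 0:
        raise ValueError("BAU total must be positive")
    return int(round(100.0 * total_averted / total_bau))


def rr_at(rr: RelativeRisk, value: float) -> RelativeRisk:
    """A copy of ``rr`` with a substituted central estimate (utility for sweeps)."""
    return replace(rr, rr=value, ci_low=min(rr.ci_low, value), ci_high=max(rr.ci_high, value))
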