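"""Regular latitude-longitude analysis grid.

All gridded objects in a run (concentration fields, population, mortality,
exposure surfaces) share one :class:`GridSpec`, a desk-scale stand-in for a
kilometre-scale CONUS modelling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr


@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid defined by its cell centers.

    Parameters
    ----------
    n_lat, n_lon
        Number of rows / columns (>= 1).
    lat0, lon0
        Center of the south-west cell, degrees.
    dlat, dlon
        Cell spacing, degrees (> 0).
    """

    n_lat: int = 40
    n_lon: int = 60
    lat0: float = 25.0
    lon0: float = -120.0
    dlat: float = 0.5
    dlon: float = 0.5

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must have at least one cell in each direction")
        if self.dlat <= 0 or self.dlon <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.dlat * np.arange(self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(self.n_lon)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def coords(self) -> dict:
        return {"lat": self.lats, "lon": self.lons}

    def surface(self, values: np.ndarray, **attrs) -> xr.DataArray:
        """Wrap a (n_lat, n_lon) array as a DataArray on this grid."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError(f"expected shape {self.shape}, got {values.shape}")
        return xr.DataArray(values, coords=self.coords(), dims=("lat", "lon"), attrs=attrs)

    def contains(self, lat: float, lon: float) -> bool:
        """True if (lat, lon) falls within the grid's cell footprint."""
        return (
            self.lat0 - self.dlat / 2 <= lat <= self.lats[-1] + self.dlat / 2
            and self.lon0 - self.dlon / 2 <= lon <= self.lons[-1] + self.dlon / 2
        )

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Indices of the cell whose center is nearest to (lat, lon)."""
        if not self.contains(lat, lon):
            raise ValueError(f"site ({lat}, {lon}) outside grid domain")
        i = int(np.clip(round((lat - self.lat0) / self.dlat), 0, self.n_lat - 1))
        j = int(np.clip(round((lon - self.lon0) / self.dlon), 0, self.n_lon - 1))
        return i, j
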