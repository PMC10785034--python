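"""Readers and writers for the pipeline's on-disk formats.

Gridded objects travel as CF-style NetCDF (dims time/lat/lon, units
attributes); inventories, activity series, pixel tables and site lists as CSV
with documented headers; run configuration as YAML/JSON.  Every writer has a
reader that reproduces the in-memory values exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import xarray as xr
import yaml

from .satellite import RetrievalPixel, frame_to_pixels, pixels_to_frame

__all__ = [
    "write_netcdf",
    "read_netcdf",
    "write_table",
    "read_inventory",
    "read_activity",
    "write_pixels",
    "read_pixels",
    "load_config",
    "save_config",
    "config_hash",
]

INVENTORY_COLUMNS = ["species", "sector", "state", "month", "value"]
ACTIVITY_COLUMNS = ["sector", "month", "scaling"]
SITE_COLUMNS = ["site_id", "lat", "lon"]


def write_netcdf(obj: xr.DataArray | xr.Dataset, path: str | Path, name: str = "data") -> Path:
    """Write a field or surface as classic NetCDF (scipy backend, netCDF3)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = obj.to_dataset(name=obj.name or name) if isinstance(obj, xr.DataArray) else obj
    ds = ds.copy()
    # netCDF3 has no booleans/objects; attrs must be primitive
    for v in ds.variables.values():
        v.attrs = {k: a for k, a in v.attrs.items() if isinstance(a, (str, int, float))}
    ds.attrs = {k: a for k, a in ds.attrs.items() if isinstance(a, (str, int, float))}
    ds.to_netcdf(path, engine="scipy")
    return path


def read_netcdf(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frame


def read_inventory(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, INVENTORY_COLUMNS)


def read_activity(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ACTIVITY_COLUMNS)


def write_pixels(pixels: list[RetrievalPixel], path: str | Path) -> Path:
    return write_table(pixels_to_frame(pixels), path)


def read_pixels(path: str | Path) -> list[RetrievalPixel]:
    return frame_to_pixels(pd.read_csv(path, float_precision="round_trip"))


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) run configuration into a plain dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def config_hash(config: dict) -> str:
    """Stable hash of a configuration dict (for the run log)."""
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
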