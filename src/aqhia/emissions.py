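"""Activity scaling of sectoral emission inventories and change accounting.

An inventory is a tidy ``pandas.DataFrame`` with columns
``species, sector, state, month, value`` (mass emitted, t/month).  Activity
series carry one multiplicative scaling per (sector, month) relative to the
reference year; a reference (business-as-usual) series is identically 1.

Group fractional changes are mass-weighted aggregates,
``sum(scaled)/sum(reference) - 1``, not averages of per-entry fractions: that
is what a "national total change" means.  Percentiles across states use linear
interpolation between closest ranks (numpy's default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "DEFAULT_UNSCALED_SECTORS",
    "ChangeTable",
    "apply_monthly_scaling",
    "fractional_change",
    "state_percentile_band",
    "period_mean_change",
]

#: the six species tracked by the accounting; others pass through with a warning
SPECIES = ("CO", "NOx", "VOC", "SO2", "NH3", "PM2.5")

#: sectors with no activity proxy; they pass through unscaled by default
DEFAULT_UNSCALED_SECTORS = frozenset({"agriculture", "fugitive_dust"})

_COLS = ["species", "sector", "state", "month", "value"]


def _check_inventory(inv: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLS if c not in inv.columns]
    if missing:
        raise ValueError(f"inventory missing columns {missing}")
    if (inv["value"] < 0).any():
        raise ValueError("emission masses must be non-negative")
    extra = set(inv["species"]) - set(SPECIES)
    if extra:
        warnings.warn(f"species outside the tracked list pass through unvalidated: {sorted(extra)}")
    return inv


def apply_monthly_scaling(
    base: pd.DataFrame,
    series: pd.DataFrame,
    unscaled_sectors: frozenset[str] | set[str] = DEFAULT_UNSCALED_SECTORS,
) -> pd.DataFrame:
    """Scale each (sector, month) of the base inventory by its activity factor.

    ``series`` has columns ``sector, month, scaling``.  Every sector in the
    base must either appear in the series or be declared in
    ``unscaled_sectors`` (those pass through unchanged).
    """
    _check_inventory(base)
    if (series["scaling"] < 0).any():
        raise ValueError("activity scalings must be non-negative")
    scaled_sectors = set(series["sector"])
    orphans = set(base["sector"]) - scaled_sectors - set(unscaled_sectors)
    if orphans:
        raise ValueError(f"sectors with neither an activity series nor an unscaled declaration: {sorted(orphans)}")
    out = base.merge(series[["sector", "month", "scaling"]], on=["sector", "month"], how="left")
    out["scaling"] = out["scaling"].fillna(1.0)
    out["value"] = out["value"] * out["scaling"]
    return out[_COLS].reset_index(drop=True)


@dataclass
class ChangeTable:
    """Fractional emission changes relative to a reference inventory.

    Each table carries the group's fractional change and the reference mass it
    is weighted by, so period aggregates stay mass-weighted.
    """

    national: pd.DataFrame  # species, month, fraction, ref
    by_sector: pd.DataFrame  # species, sector, month, fraction, ref
    by_state: pd.DataFrame  # species, state, month, fraction, ref
    reference_year: str = ""
    extras: dict = field(default_factory=dict)


def _group_fraction(scaled: pd.DataFrame, reference: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    s = scaled.groupby(keys, as_index=False)["value"].sum().rename(columns={"value": "scaled"})
    r = reference.groupby(keys, as_index=False)["value"].sum().rename(columns={"value": "ref"})
    m = r.merge(s, on=keys, how="left")
    m["scaled"] = m["scaled"].fillna(0.0)
    if (m["ref"] <= 0).any():
        bad = m.loc[m["ref"] <= 0, keys].to_dict("records")
        raise ValueError(f"zero reference total for group(s) {bad[:3]}")
    m["fraction"] = m["scaled"] / m["ref"] - 1.0
    return m[keys + ["fraction", "ref"]]


def fractional_change(scaled: pd.DataFrame, reference: pd.DataFrame, reference_year: str = "") -> ChangeTable:
    """Mass-weighted fractional changes by species x month, x sector, x state."""
    _check_inventory(scaled)
    _check_inventory(reference)
    return ChangeTable(
        national=_group_fraction(scaled, reference, ["species", "month"]),
        by_sector=_group_fraction(scaled, reference, ["species", "sector", "month"]),
        by_state=_group_fraction(scaled, reference, ["species", "state", "month"]),
        reference_year=reference_year,
    )


def state_percentile_band(
    change: ChangeTable, species: str, month: int, lo: float = 20, hi: float = 80
) -> tuple[float, float, float]:
    """(lo, hi) percentiles of state-level fractions plus the national fraction.

    A state dominating the national mass can pull the national value outside
    the band — the band describes state variability, not the total.
    """
    states = change.by_state.query("species == @species and month == @month")["fraction"].to_numpy()
    if len(states) < 2:
        raise ValueError("percentile band needs at least 2 states")
    lo_pct, hi_pct = np.percentile(states, [lo, hi])  # linear interpolation between ranks
    nat = change.national.query("species == @species and month == @month")["fraction"]
    if nat.empty:
        raise ValueError(f"no national fraction for {species} month {month}")
    return float(lo_pct), float(hi_pct), float(nat.iloc[0])


def period_mean_change(
    change: ChangeTable, species: str, months: list[int] | tuple[int, ...]
) -> tuple[float, float]:
    """Mass-weighted national fraction over a set of months, with state spread.

    The mean is the reference-mass-weighted fraction over the months (i.e.
    sum(scaled)/sum(ref) - 1 for the period).  The spread is the 1-sigma of
    per-state period fractions, states weighted equally (0 for a single
    state).
    """
    months = list(months)
    if not months:
        raise ValueError("empty month set")
    nat = change.national.query("species == @species and month in @months")
    if nat.empty:
        raise ValueError(f"no entries for {species} in months {months}")
    mean = float(np.average(nat["fraction"], weights=nat["ref"]))
    st = change.by_state.query("species == @species and month in @months")
    per_state = st.groupby("state").apply(
        lambda g: np.average(g["fraction"], weights=g["ref"]), include_groups=False
    )
    sd = float(per_state.std(ddof=1)) if len(per_state) > 1 else 0.0
    return mean, sd
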