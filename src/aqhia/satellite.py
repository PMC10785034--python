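"""Model-vs-satellite column comparison with model-consistent air-mass factors.

A retrieval pixel carries its tropospheric vertical column (VCD), the original
air-mass factor (AMF), per-layer scattering weights, and the retrieval's
a priori trace-gas profile.  For a like-for-like comparison the retrieval's
AMF is recomputed with the model profile,

    AMF_model = sum_l(sw_l * m_l) / sum_l(m_l)     (tropospheric layers),

and the column is re-derived holding the slant column fixed:
``adjusted_vcd = vcd * amf_orig / amf_model``.  Scattering-weight (TROPOMI/OMI
style) and shape-factor (OMPS style) pathways both reduce to this formula.

Regression of year-2 against year-1 columns uses orthogonal distance
regression (equal error variance on both axes), for which the exact solution
is the total-least-squares line; the slope CI uses a leave-one-out jackknife
with a normal 95% interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "RetrievalPixel",
    "filter_pixels",
    "model_column",
    "model_amf",
    "recompute_amf",
    "classify_source_region",
    "regional_change",
    "odr_fit",
    "OdrResult",
    "pixels_to_frame",
    "frame_to_pixels",
]

#: NOx-sector to region-label mapping used by the 60% dominance rule
SECTOR_LABELS = {"mobile": "urban", "point": "point", "og": "oil_and_gas"}
OTHER = "other"


@dataclass
class RetrievalPixel:
    """One satellite-style retrieval pixel."""

    lat: float
    lon: float
    vcd: float  # tropospheric vertical column, molecules cm-2
    amf_orig: float
    scattering_weights: np.ndarray  # per layer, unitless, >= 0
    apriori: np.ndarray  # per-layer partial columns, molecules cm-2
    tropopause_layer: int  # highest tropospheric layer index (0-based, inclusive)
    qa: float = 1.0
    cloud_fraction: float = 0.0
    sza: float = 0.0

    def __post_init__(self) -> None:
        self.scattering_weights = np.asarray(self.scattering_weights, dtype=float)
        self.apriori = np.asarray(self.apriori, dtype=float)
        if self.scattering_weights.shape != self.apriori.shape:
            raise ValueError("scattering weights and a priori profile must share layering")
        if np.any(self.scattering_weights < 0):
            raise ValueError("scattering weights must be non-negative")
        if not 0 <= self.tropopause_layer < len(self.apriori):
            raise ValueError("tropopause layer index out of range")

    @property
    def n_layers(self) -> int:
        return len(self.apriori)


def filter_pixels(
    pixels: list[RetrievalPixel], qa_min: float = 0.75, cf_max: float = 0.3, sza_max: float = 70.0
) -> list[RetrievalPixel]:
    """Quality screening: keep qa >= qa_min, cloud <= cf_max, sza <= sza_max."""
    return [p for p in pixels if p.qa >= qa_min and p.cloud_fraction <= cf_max and p.sza <= sza_max]


def model_column(profile: np.ndarray, tropopause_layer: int) -> float:
    """Tropospheric vertical column: sum of partial columns up to the tropopause."""
    profile = np.asarray(profile, dtype=float)
    if not 0 <= tropopause_layer < len(profile):
        raise ValueError("tropopause layer index out of range")
    return float(profile[: tropopause_layer + 1].sum())


def model_amf(scattering_weights: np.ndarray, profile: np.ndarray, tropopause_layer: int) -> float:
    """Profile-weighted mean scattering weight over the tropospheric layers."""
    sw = np.asarray(scattering_weights, dtype=float)[: tropopause_layer + 1]
    m = np.asarray(profile, dtype=float)[: tropopause_layer + 1]
    if np.any(sw < 0):
        raise ValueError("scattering weights must be non-negative")
    tot = m.sum()
    if tot <= 0:
        raise ValueError("model profile has zero tropospheric column")
    return float(np.dot(sw, m) / tot)


def recompute_amf(pixel: RetrievalPixel, model_profile: np.ndarray) -> float:
    """Vertical column re-derived with a model-profile AMF, slant column fixed.

    The implied slant column vcd * amf is invariant:
    adjusted_vcd * amf_model == vcd * amf_orig.
    """
    amf_m = model_amf(pixel.scattering_weights, model_profile, pixel.tropopause_layer)
    return float(pixel.vcd * pixel.amf_orig / amf_m)


def classify_source_region(
    sector_fractions: dict[str, np.ndarray] | xr.Dataset, threshold: float = 0.60
) -> xr.DataArray | np.ndarray:
    """Label each cell by its dominant NOx source sector.

    A cell is 'urban' / 'point' / 'oil_and_gas' when the mobile / point / O&G
    share of its NOx emissions is at least ``threshold`` (inclusive), 'other'
    otherwise.  With threshold > 0.5 at most one sector can qualify.
    """
    as_dataset = isinstance(sector_fractions, xr.Dataset)
    fracs = {k: np.asarray(sector_fractions[k]) for k in SECTOR_LABELS if k in sector_fractions}
    if not fracs:
        raise ValueError("need at least one of the sectors " + ", ".join(SECTOR_LABELS))
    stack = np.stack(list(fracs.values()))
    if np.any((stack < 0) | (stack > 1)):
        raise ValueError("sector fractions must lie in [0, 1]")
    if np.any(stack.sum(axis=0) > 1.0 + 1e-9):
        raise ValueError("sector fractions sum to more than 1")
    labels = np.full(stack.shape[1:], OTHER, dtype=object)
    best = np.argmax(stack, axis=0)
    qualifies = np.take_along_axis(stack, best[None], axis=0)[0] >= threshold
    names = np.array([SECTOR_LABELS[k] for k in fracs], dtype=object)
    labels[qualifies] = names[best][qualifies]
    if as_dataset:
        template = sector_fractions[list(fracs)[0]]
        return xr.DataArray(labels, coords=template.coords, dims=template.dims, attrs={"metric": "source_region"})
    return labels


def regional_change(
    columns_y1: xr.DataArray, columns_y2: xr.DataArray, labels: xr.DataArray | np.ndarray, region: str
) -> float:
    """Fractional change of the region-mean column between two periods."""
    lab = np.asarray(labels)
    sel = lab == region
    if not sel.any():
        raise ValueError(f"no cells labelled {region!r}")
    y1 = np.asarray(columns_y1.values, dtype=float)[sel]
    y2 = np.asarray(columns_y2.values, dtype=float)[sel]
    keep = np.isfinite(y1) & np.isfinite(y2)
    if not keep.any():
        raise ValueError(f"no valid column pairs in region {region!r}")
    m1 = y1[keep].mean()
    if m1 == 0:
        raise ValueError("zero reference-period mean column")
    return float((y2[keep].mean() - m1) / m1)


@dataclass
class OdrResult:
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    n: int = 0


def _tls_slope(x: np.ndarray, y: np.ndarray) -> float:
    # exact orthogonal (total least squares) slope for equal error variances
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    if sxy == 0:
        if syy == sxx:
            raise ValueError("degenerate data: orthogonal slope undefined")
        return 0.0 if sxx > syy else np.inf
    return (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)


def odr_fit(x: np.ndarray, y: np.ndarray) -> OdrResult:
    """Orthogonal distance regression line with a jackknife 95% slope CI.

    Minimizes the sum of squared perpendicular distances assuming equal error
    variance on both axes; the closed-form solution is the major axis of the
    point cloud.  The slope standard error is estimated by leave-one-out
    jackknife and turned into a normal-approximation 95% interval (exact-fit
    data gives a zero-width interval).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("ODR needs at least 3 points")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate data: all points identical")
    slope = _tls_slope(x, y)
    intercept = float(y.mean() - slope * x.mean())

    idx = np.arange(n)
    loo = np.empty(n)
    for i in range(n):
        keep = idx != i
        loo[i] = _tls_slope(x[keep], y[keep])
    se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
    half = 1.959963984540054 * se
    return OdrResult(slope=float(slope), intercept=intercept, slope_ci95=(float(slope - half), float(slope + half)), n=n)


# ---------------------------------------------------------------------------
# CSV round trip: one row per pixel, layer profiles JSON-encoded


def pixels_to_frame(pixels: list[RetrievalPixel]) -> pd.DataFrame:
    rows = []
    for p in pixels:
        rows.append(
            {
                "lat": p.lat,
                "lon": p.lon,
                "vcd": p.vcd,
                "amf_orig": p.amf_orig,
                "tropopause_layer": p.tropopause_layer,
                "qa": p.qa,
                "cloud_fraction": p.cloud_fraction,
                "sza": p.sza,
                "scattering_weights": json.dumps(list(p.scattering_weights)),
                "apriori": json.dumps(list(p.apriori)),
            }
        )
    return pd.DataFrame(rows)


def frame_to_pixels(frame: pd.DataFrame) -> list[RetrievalPixel]:
    return [
        RetrievalPixel(
            lat=row.lat,
            lon=row.lon,
            vcd=row.vcd,
            amf_orig=row.amf_orig,
            scattering_weights=np.array(json.loads(row.scattering_weights)),
            apriori=np.array(json.loads(row.apriori)),
            tropopause_layer=int(row.tropopause_layer),
            qa=row.qa,
            cloud_fraction=row.cloud_fraction,
            sza=row.sza,
        )
        for row in frame.itertuples()
    ]
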