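"""Validation of combined origin maps against independent evidence.

A combined origin surface is scored four ways: (1) a Welch t contrast of
chlorophyll-a concentration between the map's top-quantile cells and the
rest (food-availability check); (2) the d13C-latitude relation
d13C = -8.52 - 0.26 x latitude(degrees South), inverted to predict a
moulting latitude band whose origin scores are compared to the map's 95%
quantile (valid only south of the Subtropical Front near 44 degrees S);
(3) mean origin scores inside great-circle buffers around binned sighting
locations, compared to the map's own 50%/95% quantiles; and (4) mean origin
scores per marine eco-realm polygon, classified against the same quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .assign import OriginSurface, quantile_mask
from .ctree import TestResult, welch_t
from .grid import Isoscape
from .io import Region

__all__ = [
    "EARTH_RADIUS_M", "ValidationReport",
    "chlorophyll_contrast", "predict_latitude", "latitude_band_stats",
    "bin_observations", "buffer_extract", "region_scores",
]

EARTH_RADIUS_M = 6_371_000.0

# d13C-latitude relation coefficients (latitude in degrees South magnitude)
LAT_EQ_INTERCEPT = -8.52
LAT_EQ_SLOPE = 0.26
STF_LATITUDE = -44.0   # Subtropical Front; predictions north of it are flagged


@dataclass
class ValidationReport:
    """Bundle of the verification outputs for one combined surface."""

    q50: float
    q75: float
    q95: float
    chl_test: TestResult | None = None
    per_point: pd.DataFrame | None = None
    per_region: pd.DataFrame | None = None
    latitude_band: dict | None = None

    def __post_init__(self):
        if not (self.q50 <= self.q75 <= self.q95):
            raise ValueError("quantiles out of order")


# ---------------------------------------------------------------------------

def chlorophyll_contrast(surface: OriginSurface, chl: Isoscape,
                         q: float = 0.75) -> TestResult:
    """Welch t of chlorophyll in high-origin-score vs low-score areas.

    Cells are partitioned at the surface's q-quantile; orientation is
    high-area minus low-area, so a positive t means the predicted moulting
    area is richer in chlorophyll.
    """
    if surface.values.shape != chl.values.shape:
        raise ValueError("surface and chlorophyll grids differ in geometry")
    threshold, high = quantile_mask(surface, q)
    low = surface.mask & ~high
    a = chl.values[high & chl.mask]
    b = chl.values[low & chl.mask]
    if a.size < 2 or b.size < 2:
        raise ValueError("quantile partition left a group with < 2 ocean cells")
    return welch_t(a, b)


def predict_latitude(d13c_feather: float):
    """Moulting latitude (signed degrees, south negative) from feather d13C.

    Inverts d13C = -8.52 - 0.26 x lat(degrees S): lat_S = (-8.52 - d13C)/0.26,
    returned as a negative signed latitude. Returns ``(latitude,
    north_of_stf)``; when the prediction falls north of the Subtropical
    Front (latitude > -44) the flag is set and band statistics should not
    be extracted.
    """
    lat_s = (LAT_EQ_INTERCEPT - float(d13c_feather)) / LAT_EQ_SLOPE
    latitude = -lat_s
    return latitude, bool(latitude > STF_LATITUDE)


def latitude_band_stats(surface: OriginSurface, lat_mean: float, lat_sd: float):
    """Max/mean/SD of origin scores in the band lat_mean +/- lat_sd, with a
    comparison to the surface's own 95% quantile."""
    lo, hi = lat_mean - lat_sd, lat_mean + lat_sd
    in_band = (surface.lats >= lo) & (surface.lats <= hi)
    cells = surface.mask & in_band[:, None]
    vals = surface.values[cells]
    if vals.size == 0:
        raise ValueError(f"latitude band [{lo}, {hi}] contains no ocean cells")
    q95 = surface.quantile(0.95)
    band_max = float(vals.max())
    band_mean = float(vals.mean())
    band_sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return {
        "band_max": band_max,
        "band_mean": band_mean,
        "band_sd": band_sd,
        "q95": q95,
        "max_exceeds_q95": band_max > q95,
        "mean_band_exceeds_q95": band_mean + band_sd > q95,
    }


def bin_observations(points, cell_deg: float = 10.0) -> pd.DataFrame:
    """Average sighting locations within cell_deg x cell_deg bins.

    The binning grid is anchored at (-90, -180). Returns one centroid row
    per non-empty bin with columns lat, lon, n; the n column sums to the
    input count.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        return pd.DataFrame(columns=["lat", "lon", "n"])
    lat_bin = np.floor((pts[:, 0] + 90.0) / cell_deg).astype(int)
    lon_bin = np.floor((pts[:, 1] + 180.0) / cell_deg).astype(int)
    df = pd.DataFrame({"lat": pts[:, 0], "lon": pts[:, 1],
                       "lat_bin": lat_bin, "lon_bin": lon_bin})
    out = (df.groupby(["lat_bin", "lon_bin"], sort=True)
             .agg(lat=("lat", "mean"), lon=("lon", "mean"), n=("lat", "size"))
             .reset_index(drop=True))
    return out


def _great_circle_m(lat1, lon1, lat2, lon2):
    """Haversine distance in metres on a spherical Earth."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def buffer_extract(surface, centroids: pd.DataFrame,
                   radius_m: float = 1.1e6) -> pd.DataFrame:
    """Mean field value within a great-circle buffer around each centroid.

    ``surface`` may be an OriginSurface or an Isoscape. Points whose buffer
    contains no ocean cell get a missing score (they are reported, not
    dropped). The returned frame also carries ``mean``/``sd`` across points
    in its attrs.
    """
    lat_g = np.broadcast_to(np.asarray(surface.lats)[:, None], surface.values.shape)
    lon_g = np.broadcast_to(np.asarray(surface.lons)[None, :], surface.values.shape)
    rows = []
    for _, pt in centroids.iterrows():
        dist = _great_circle_m(pt["lat"], pt["lon"], lat_g, lon_g)
        inside = surface.mask & (dist <= radius_m)
        vals = surface.values[inside]
        rows.append({"lat": pt["lat"], "lon": pt["lon"],
                     "n_cells": int(inside.sum()),
                     "mean_score": float(vals.mean()) if vals.size else np.nan})
    out = pd.DataFrame(rows, columns=["lat", "lon", "n_cells", "mean_score"])
    scores = out["mean_score"].dropna()
    out.attrs["mean"] = float(scores.mean()) if len(scores) else np.nan
    out.attrs["sd"] = float(scores.std(ddof=1)) if len(scores) > 1 else np.nan
    return out


def region_scores(surface: OriginSurface, regions: list[Region],
                  q50: float | None = None, q95: float | None = None) -> pd.DataFrame:
    """Mean +/- SD of ocean-cell scores per region polygon, classified
    against the surface's 50%/95% quantiles.

    Cell membership is by cell center; a center on a shared boundary goes
    to the first-listed region containing it. Regions with no ocean cells
    are reported with class ``unavailable``.
    """
    q50 = surface.quantile(0.50) if q50 is None else q50
    q95 = surface.quantile(0.95) if q95 is None else q95
    lat_g = np.broadcast_to(surface.lats[:, None], surface.values.shape)
    lon_g = np.broadcast_to(surface.lons[None, :], surface.values.shape)
    unclaimed = surface.mask.copy()
    rows = []
    for region in regions:
        shapely.prepare(region.geometry)
        inside = shapely.contains_xy(
            region.geometry, lon_g.ravel(), lat_g.ravel()
        ).reshape(surface.values.shape)
        boundary = shapely.boundary(region.geometry)
        on_edge = shapely.intersects_xy(
            boundary, lon_g.ravel(), lat_g.ravel()).reshape(surface.values.shape)
        cells = (inside | on_edge) & unclaimed
        unclaimed &= ~cells
        vals = surface.values[cells]
        if vals.size == 0:
            rows.append({"region": region.name, "n_cells": 0,
                         "mean": np.nan, "sd": np.nan, "class": "unavailable"})
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        cls = "above_q95" if mean > q95 else ("below_q50" if mean < q50 else "mid")
        rows.append({"region": region.name, "n_cells": int(vals.size),
                     "mean": mean, "sd": sd, "class": cls})
    out = pd.DataFrame(rows)
    out.attrs["q50"] = q50
    out.attrs["q95"] = q95
    return out
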