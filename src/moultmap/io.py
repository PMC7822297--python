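"""Readers and writers for the pipeline's tabular, raster and vector inputs.

Formats: CSV for per-bird feather records, ESRI ASCII grid (plain text) for
rasters, GeoJSON for region polygons. All readers fail loudly on malformed
input; missing table cells become proper missing markers, never zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .grid import Isoscape, normalize_lon

__all__ = [
    "RECORD_COLUMNS", "REQUIRED_COLUMNS", "Region",
    "read_records", "write_records", "read_raster", "write_raster",
    "read_regions", "write_regions", "restrict_extent",
]

#: Canonical record columns (one row = one bird).
RECORD_COLUMNS = [
    "id", "species", "year", "sex",
    "d13C_raw", "d15N", "d18O_raw",
    "fgr", "body_mass", "tarsus", "wing",
]
#: Columns that must be present (possibly via column_map) in any input table.
REQUIRED_COLUMNS = ["species", "d13C_raw", "d18O_raw"]
#: Columns appended by downstream stages.
DERIVED_COLUMNS = ["d13C_corr", "d18O_corr", "group_label",
                   "origin_lat", "origin_lon"]

_CATEGORICAL = ["id", "species", "year", "sex", "group_label"]


@dataclass
class Region:
    """A named region polygon in lon/lat degrees (GeoJSON axis order)."""

    name: str
    geometry: object  # shapely (Multi)Polygon

    def __post_init__(self):
        if not self.geometry.is_valid:
            raise ValueError(f"region {self.name!r}: invalid (self-intersecting?) polygon")


# ---------------------------------------------------------------------------
# records (CSV)
# ---------------------------------------------------------------------------

def read_records(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a feather-record table into the canonical column schema.

    Parameters
    ----------
    path : str or Path
        CSV file, one row per bird.
    column_map : dict, optional
        Maps canonical names (keys) to the file's column headers (values),
        e.g. ``{"d13C_raw": "d13C"}``. Unmapped canonical names are looked
        up verbatim.

    Returns
    -------
    DataFrame with the canonical columns; absent optional columns are filled
    with missing values. Row count equals the file's row count.
    """
    df = pd.read_csv(path, dtype={c: "string" for c in _CATEGORICAL})
    column_map = column_map or {}
    rename = {}
    for canonical in RECORD_COLUMNS + DERIVED_COLUMNS:
        src = column_map.get(canonical, canonical)
        if src in df.columns:
            rename[src] = canonical
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing required columns: {missing}")

    out = pd.DataFrame(index=df.index)
    for col in RECORD_COLUMNS + DERIVED_COLUMNS:
        if col in df.columns:
            out[col] = df[col]
        elif col in _CATEGORICAL:
            out[col] = pd.Series(pd.NA, index=df.index, dtype="string")
        else:
            out[col] = np.nan
    if out["id"].isna().all():
        out["id"] = [f"r{i}" for i in range(len(out))]
    for col in out.columns:
        if col not in _CATEGORICAL:
            out[col] = pd.to_numeric(out[col], errors="coerce")
        else:
            out[col] = out[col].astype("string")
    for col in ("d13C_raw", "d15N", "d18O_raw"):
        vals = out[col].to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValueError(f"non-finite isotope value in column {col}")
    return out


def write_records(records: pd.DataFrame, path) -> None:
    cols = [c for c in RECORD_COLUMNS + DERIVED_COLUMNS if c in records.columns]
    records.to_csv(path, columns=cols, index=False)


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_raster(iso: Isoscape, path) -> None:
    """Write an isoscape as an ESRI ASCII grid; masked cells become NODATA.

    A non-scalar SD layer is written beside it as ``<stem>.sd.asc``;
    a scalar SD is recorded in a one-line ``<stem>.sd.txt``.
    """
    path = Path(path)
    _write_asc(path, iso)
    if iso.sd is not None:
        if np.isscalar(iso.sd):
            path.with_suffix(".sd.txt").write_text(f"{float(iso.sd):.10g}\n")
        else:
            sd_iso = Isoscape(iso.sd_grid(), iso.lats, iso.lons, iso.mask)
            _write_asc(path.with_suffix(".sd.asc"), sd_iso)


def _write_asc(path: Path, iso: Isoscape) -> None:
    res = iso.resolution
    vals = np.where(iso.mask, iso.values, _NODATA)
    header = (
        f"ncols {iso.lons.size}\n"
        f"nrows {iso.lats.size}\n"
        f"xllcorner {iso.lons[0] - res / 2:.10g}\n"
        f"yllcorner {iso.lats[-1] - res / 2:.10g}\n"
        f"cellsize {res:.10g}\n"
        f"NODATA_value {_NODATA:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.9g")


def read_raster(path) -> Isoscape:
    """Read an ESRI ASCII grid (and any SD sidecar) back into an Isoscape.

    The grid must be in geographic lat/lon degrees; anything resembling
    projected coordinates (|corner| beyond the globe) is rejected rather
    than silently reinterpreted.
    """
    path = Path(path)
    values, lats, lons = _read_asc(path)
    mask = values != _NODATA
    values = np.where(mask, values, np.nan)
    sd = None
    sd_asc = path.with_suffix(".sd.asc")
    sd_txt = path.with_suffix(".sd.txt")
    if sd_asc.exists():
        sd_vals, _, _ = _read_asc(sd_asc)
        sd = np.where(sd_vals == _NODATA, np.nan, sd_vals)
    elif sd_txt.exists():
        sd = float(sd_txt.read_text().strip())
    return Isoscape(values, lats, lons, mask, sd)


def _read_asc(path: Path):
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    res = header["cellsize"]
    x0, y0 = header["xllcorner"], header["yllcorner"]
    if not (-360.0 <= x0 <= 360.0 and -90.0 <= y0 <= 90.0):
        raise ValueError(
            f"{path}: corner ({x0}, {y0}) is not geographic lat/lon; "
            "reprojection is not supported"
        )
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data block {values.shape} != header ({nrows}, {ncols})")
    lats = y0 + res * (np.arange(nrows)[::-1] + 0.5)
    lons = normalize_lon(x0 + res * (np.arange(ncols) + 0.5))
    return values, lats, np.asarray(lons)


# ---------------------------------------------------------------------------
# regions (GeoJSON)
# ---------------------------------------------------------------------------

def read_regions(path) -> list[Region]:
    with open(path) as fh:
        gj = json.load(fh)
    regions = []
    for feat in gj["features"]:
        name = feat.get("properties", {}).get("name", f"region{len(regions)}")
        regions.append(Region(name, shape(feat["geometry"])))
    return regions


def write_regions(regions: list[Region], path) -> None:
    feats = [
        {"type": "Feature", "properties": {"name": r.name},
         "geometry": mapping(r.geometry)}
        for r in regions
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# extent windows
# ---------------------------------------------------------------------------

def restrict_extent(iso: Isoscape, lon_min: float, lon_max: float) -> Isoscape:
    """Mask ocean cells outside a longitude window; geometry is unchanged.

    The window may wrap the antimeridian (``lon_min > lon_max`` after
    normalisation selects lon >= lon_min OR lon <= lon_max).
    """
    lon_min = float(normalize_lon(lon_min))
    lon_max = float(normalize_lon(lon_max))
    if lon_min == lon_max:
        raise ValueError("empty longitude window")
    if lon_min < lon_max:
        inside = (iso.lons >= lon_min) & (iso.lons <= lon_max)
    else:  # wraps the antimeridian
        inside = (iso.lons >= lon_min) | (iso.lons <= lon_max)
    out = iso.copy()
    out.mask = out.mask & inside[None, :]
    return out
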