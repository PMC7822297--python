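"""Gridded isoscape container.

An :class:`Isoscape` is a rectangular lat/lon grid of per-mil isotope values
(or any other per-cell scalar, e.g. chlorophyll-a concentration in mg m^-3)
with an ocean mask and, optionally, a per-cell standard-deviation layer.

Grid convention (fixed package-wide): cells are center-registered, latitude
rows run north -> south (row 0 is the northernmost row), longitudes run
west -> east and are normalised to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Isoscape", "normalize_lon"]


def normalize_lon(lon):
    """Map longitudes into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    out = np.where(out == -180.0, 180.0, out)
    return out if out.ndim else float(out)


@dataclass
class Isoscape:
    """A 2-D gridded field with ocean mask and optional SD layer.

    Parameters
    ----------
    values : ndarray, shape (nlat, nlon)
        Cell values. May contain NaN only on masked (land) cells.
    lats : ndarray, shape (nlat,)
        Cell-center latitudes, strictly decreasing (north to south).
    lons : ndarray, shape (nlon,)
        Cell-center longitudes, strictly increasing, in (-180, 180].
    mask : ndarray of bool, shape (nlat, nlon)
        True on ocean cells, False on land.
    sd : ndarray or float or None
        Per-cell standard deviation of the field (same units as values);
        a scalar is broadcast; None means no SD layer.
    """

    values: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    mask: np.ndarray
    sd: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.lats.size, self.lons.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.lats.size}, {self.lons.size})"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        if self.lats.size > 1 and not np.all(np.diff(self.lats) < 0):
            raise ValueError("lats must be strictly decreasing (north to south)")
        if self.lons.size > 1 and not np.all(np.diff(self.lons) > 0):
            raise ValueError("lons must be strictly increasing")
        if np.any(~np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values on unmasked (ocean) cells")
        if self.sd is not None:
            sd_arr = np.broadcast_to(np.asarray(self.sd, dtype=float), self.values.shape)
            if np.any(sd_arr[self.mask] < 0):
                raise ValueError("sd must be >= 0")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self):
        return self.values.shape

    @property
    def resolution(self):
        if self.lats.size > 1:
            return float(abs(self.lats[1] - self.lats[0]))
        if self.lons.size > 1:
            return float(self.lons[1] - self.lons[0])
        raise ValueError("single-cell grid has no defined resolution")

    def same_geometry(self, other: "Isoscape") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lats, other.lats)
            and np.allclose(self.lons, other.lons)
            and np.array_equal(self.mask, other.mask)
        )

    def cell_index(self, lat: float, lon: float):
        """Row/col of the cell whose center is nearest (lat, lon)."""
        lon = normalize_lon(lon)
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return i, j

    def value_at(self, lat: float, lon: float) -> float:
        i, j = self.cell_index(lat, lon)
        return float(self.values[i, j])

    def sd_grid(self) -> np.ndarray | None:
        if self.sd is None:
            return None
        return np.broadcast_to(np.asarray(self.sd, dtype=float), self.shape).copy()

    def ocean_values(self) -> np.ndarray:
        """Flat array of values on ocean cells."""
        return self.values[self.mask]

    def n_ocean(self) -> int:
        return int(self.mask.sum())

    def require_ocean(self):
        if self.n_ocean() == 0:
            raise ValueError("no ocean cells in grid")

    def lat_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lats[:, None], self.shape)

    def lon_grid(self) -> np.ndarray:
        return np.broadcast_to(self.lons[None, :], self.shape)

    def copy(self) -> "Isoscape":
        sd = None
        if self.sd is not None:
            sd = self.sd if np.isscalar(self.sd) else np.array(self.sd, dtype=float)
        return Isoscape(self.values.copy(), self.lats.copy(), self.lons.copy(),
                        self.mask.copy(), sd)


def grid_axes(lat_min, lat_max, lon_min, lon_max, resolution):
    """Cell-center axes for an extent; lats north->south, lons west->east.

    Raises on degenerate (zero-cell) extents.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if lat_max <= lat_min or lon_max <= lon_min:
        raise ValueError("degenerate extent: zero cells")
    half = resolution / 2.0
    lats = np.arange(lat_max - half, lat_min, -resolution)
    lons = np.arange(lon_min + half, lon_max, resolution)
    if lats.size == 0 or lons.size == 0:
        raise ValueError("degenerate extent: zero cells")
    return lats, normalize_lon(lons) if np.any(lons > 180) else lons
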