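"""Synthetic data with the statistical structure the assignment pipeline assumes.

This module generates every input the analysis needs — ocean isoscapes for
d13C and d18O, a chlorophyll-a field, per-bird feather records with group
structure and morphometric covariates, sighting locations, and toy marine
eco-realm polygons — so each downstream stage can be exercised and its
parameter-recovery behaviour measured without any external data.

The generative model, briefly:

* the d13C isoscape follows the Southern-Ocean latitude relation
  d13C = intercept - slope * |lat| (defaults -8.52, 0.26 per degree),
  optionally tilted zonally;
* the d18O isoscape is a smooth equator-to-pole gradient with optional
  localized coastal freshwater depressions (estuary analogues);
* a feather grown at ocean cell c carries
  d13C = isoscape_C(c) + trophic_levels * enrichment + year effect + noise,
  d18O = isoscape_O(c) + discrimination + year effect + noise,
  with Gaussian analytical noise (defaults 0.10 permil for d13C/d15N and
  0.50 permil for d18O);
* groups of birds have distinct origin centers and distinct d15N and
  morphometric means, so a conditional inference tree can rediscover the
  grouping; sex is simulated with zero effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .grid import Isoscape, grid_axes
from .io import RECORD_COLUMNS, Region

import pandas as pd

__all__ = [
    "SimConfig", "make_isoscape", "simulate_individuals",
    "make_chlorophyll", "simulate_observations", "make_ecorealms",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic world (southern-hemisphere default).

    Per-group sequences must all have length ``n_groups``
    (= ``len(group_centers)``).
    """

    # grid extent (degrees) and resolution
    lat_min: float = -75.0
    lat_max: float = -5.0
    lon_min: float = -75.0
    lon_max: float = 25.0
    resolution: float = 1.0
    #: land boxes (lat_min, lat_max, lon_min, lon_max); everything else is ocean
    land_boxes: tuple = ((-35.0, -5.0, 12.0, 25.0),)

    # group structure (centers on cell centers; dispersion at the grid scale)
    group_centers: tuple = ((-52.5, -20.5), (-30.5, -45.5))
    group_spread: float = 1.0            # deg, bivariate Gaussian origin draw
    species: tuple = ("BBSP", "WSP")     # per group
    group_d13c_offsets: tuple = (0.0, 0.0)   # permil, added on top of isoscape
    group_d18o_offsets: tuple = (0.0, 0.0)

    # covariates (per-group means, common SDs)
    d15n_means: tuple = (13.5, 15.8)
    d15n_sd: float = 0.6
    tarsus_means: tuple = (22.8, 24.2)
    tarsus_sd: float = 0.8
    wing_means: tuple = (152.0, 158.0)
    wing_sd: float = 4.0
    mass_means: tuple = (28.0, 32.0)
    mass_sd: float = 2.0
    fgr_means: tuple = (2.3, 2.6)
    fgr_sd: float = 0.3
    years: tuple = ("2017", "2018")
    year_effect_c: float = -0.15         # added to d13C in the later year
    year_effect_o: float = -0.5

    # analytical noise (one SD, permil)
    noise_sd_c: float = 0.10
    noise_sd_o: float = 0.50

    # feather <- environment offsets
    trophic_levels: int = 2
    enrichment_per_level: float = 0.8    # permil per trophic level (d13C)
    d18o_discrimination: float = 13.0    # permil, water -> feather (southern)

    # isoscape shape
    d13c_intercept: float = -8.52
    d13c_lat_slope: float = 0.26         # permil per degree of |latitude|
    d13c_lon_slope: float = 0.0
    d18o_equator: float = 0.5            # permil at the equator
    d18o_pole_drop: float = 5.0          # permil lost from equator to pole
    d18o_lon_slope: float = 0.01
    #: (lat, lon, amplitude permil, scale deg) freshwater depressions
    freshwater_depressions: tuple = ()
    isoscape_sd: float | None = None     # constant per-cell SD layer, or None

    # chlorophyll
    chl_background: float = 0.2          # mg m^-3
    chl_amplitude: float = 1.5
    chl_scale: float = 6.0               # deg

    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        for name in ("noise_sd_c", "noise_sd_o", "d15n_sd", "tarsus_sd",
                     "wing_sd", "mass_sd", "fgr_sd", "group_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        for name in ("species", "group_d13c_offsets", "group_d18o_offsets",
                     "d15n_means", "tarsus_means", "wing_means", "mass_means",
                     "fgr_means"):
            if len(getattr(self, name)) != self.n_groups:
                raise ValueError(f"{name} must have one entry per group")

    @property
    def n_groups(self) -> int:
        return len(self.group_centers)

    def axes(self):
        return grid_axes(self.lat_min, self.lat_max,
                         self.lon_min, self.lon_max, self.resolution)

    def ocean_mask(self, lats, lons):
        mask = np.ones((lats.size, lons.size), dtype=bool)
        lat_g = lats[:, None]
        lon_g = lons[None, :]
        for (la0, la1, lo0, lo1) in self.land_boxes:
            land = (lat_g >= la0) & (lat_g <= la1) & (lon_g >= lo0) & (lon_g <= lo1)
            mask &= ~land
        return mask


def make_isoscape(cfg: SimConfig, isotope: str) -> Isoscape:
    """Deterministic gridded isoscape for ``isotope`` in {"C13", "O18"}."""
    lats, lons = cfg.axes()
    lat_g = np.broadcast_to(lats[:, None], (lats.size, lons.size)).astype(float)
    lon_g = np.broadcast_to(lons[None, :], (lats.size, lons.size)).astype(float)
    if isotope == "C13":
        values = (cfg.d13c_intercept
                  - cfg.d13c_lat_slope * np.abs(lat_g)
                  + cfg.d13c_lon_slope * lon_g)
    elif isotope == "O18":
        values = (cfg.d18o_equator
                  - cfg.d18o_pole_drop * np.abs(lat_g) / 90.0
                  + cfg.d18o_lon_slope * lon_g)
        for (la, lo, amp, scale) in cfg.freshwater_depressions:
            d2 = (lat_g - la) ** 2 + (lon_g - lo) ** 2
            values = values - amp * np.exp(-d2 / (2.0 * scale ** 2))
    else:
        raise ValueError(f"unknown isotope {isotope!r} (expected 'C13' or 'O18')")
    mask = cfg.ocean_mask(lats, lons)
    return Isoscape(values, lats, lons, mask, cfg.isoscape_sd)


def _draw_origin(rng, cfg, center, iso: Isoscape, gidx: int):
    """Rejection-sample an ocean cell near a group center; returns (i, j)."""
    for _ in range(10_000):
        lat = rng.normal(center[0], cfg.group_spread) if cfg.group_spread > 0 else center[0]
        lon = rng.normal(center[1], cfg.group_spread) if cfg.group_spread > 0 else center[1]
        if not (iso.lats.min() - 0.5 * cfg.resolution <= lat <= iso.lats.max() + 0.5 * cfg.resolution):
            continue
        if not (iso.lons.min() - 0.5 * cfg.resolution <= lon <= iso.lons.max() + 0.5 * cfg.resolution):
            continue
        i, j = iso.cell_index(lat, lon)
        if iso.mask[i, j]:
            return i, j
    raise RuntimeError(f"group {gidx}: could not draw an ocean origin near {center}")


def simulate_individuals(cfg: SimConfig, isoC: Isoscape, isoO: Isoscape,
                         n_per_group, seed: int | None = None) -> pd.DataFrame:
    """Simulate feather records with known true origins.

    Returns a DataFrame in the canonical record schema plus ``group_true``
    and ``origin_lat``/``origin_lon`` (the true origin cell center).
    """
    if not isoC.same_geometry(isoO):
        raise ValueError("isoscapes do not share geometry")
    if np.isscalar(n_per_group):
        n_per_group = [int(n_per_group)] * cfg.n_groups
    if len(n_per_group) != cfg.n_groups:
        raise ValueError("n_per_group must be scalar or one entry per group")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    for g, center in enumerate(cfg.group_centers):
        i, j = isoC.cell_index(*center)
        if not isoC.mask[i, j]:
            raise ValueError(f"group {g} center {center} lies on a masked (land) cell")

    rows = []
    counter = 0
    for g, center in enumerate(cfg.group_centers):
        for _ in range(n_per_group[g]):
            i, j = _draw_origin(rng, cfg, center, isoC, g)
            year = cfg.years[rng.integers(len(cfg.years))]
            late = 1.0 if year == cfg.years[-1] and len(cfg.years) > 1 else 0.0
            d13c = (isoC.values[i, j]
                    + cfg.trophic_levels * cfg.enrichment_per_level
                    + cfg.group_d13c_offsets[g]
                    + cfg.year_effect_c * late
                    + (rng.normal(0.0, cfg.noise_sd_c) if cfg.noise_sd_c > 0 else 0.0))
            d18o = (isoO.values[i, j]
                    + cfg.d18o_discrimination
                    + cfg.group_d18o_offsets[g]
                    + cfg.year_effect_o * late
                    + (rng.normal(0.0, cfg.noise_sd_o) if cfg.noise_sd_o > 0 else 0.0))
            rows.append({
                "id": f"sim{counter}",
                "species": cfg.species[g],
                "year": year,
                "sex": ("F", "M")[rng.integers(2)],
                "d13C_raw": d13c,
                "d15N": rng.normal(cfg.d15n_means[g], cfg.d15n_sd),
                "d18O_raw": d18o,
                "fgr": rng.normal(cfg.fgr_means[g], cfg.fgr_sd),
                "body_mass": rng.normal(cfg.mass_means[g], cfg.mass_sd),
                "tarsus": rng.normal(cfg.tarsus_means[g], cfg.tarsus_sd),
                "wing": rng.normal(cfg.wing_means[g], cfg.wing_sd),
                "group_true": f"G{g + 1}",
                "origin_lat": float(isoC.lats[i]),
                "origin_lon": float(isoC.lons[j]),
            })
            counter += 1
    if not rows:
        return pd.DataFrame(columns=RECORD_COLUMNS + ["group_true", "origin_lat", "origin_lon"])
    df = pd.DataFrame(rows)
    for col in ("id", "species", "year", "sex", "group_true"):
        df[col] = df[col].astype("string")
    return df


def make_chlorophyll(cfg: SimConfig, hotspot_centers,
                     amplitude: float | None = None,
                     background: float | None = None,
                     scale: float | None = None) -> Isoscape:
    """Non-negative chlorophyll-a field: Gaussian bumps over a low background."""
    amplitude = cfg.chl_amplitude if amplitude is None else amplitude
    background = cfg.chl_background if background is None else background
    scale = cfg.chl_scale if scale is None else scale
    lats, lons = cfg.axes()
    lat_g = np.broadcast_to(lats[:, None], (lats.size, lons.size)).astype(float)
    lon_g = np.broadcast_to(lons[None, :], (lats.size, lons.size)).astype(float)
    values = np.full(lat_g.shape, float(background))
    for (la, lo) in hotspot_centers:
        d2 = (lat_g - la) ** 2 + (lon_g - lo) ** 2
        values = values + amplitude * np.exp(-d2 / (2.0 * scale ** 2))
    return Isoscape(values, lats, lons, cfg.ocean_mask(lats, lons))


def simulate_observations(surface, n: int, effort_bias=None, seed: int = 0):
    """Sample ``n`` sighting locations with probability proportional to
    ``surface x effort_bias`` over ocean cells, jittered within-cell.

    ``surface`` may be an Isoscape or an OriginSurface-like object exposing
    ``values``, ``mask``, ``lats``, ``lons``; values must be non-negative
    (use a raw normalized surface, not a centered/scaled one).
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(surface.values, dtype=float)
    mask = np.asarray(surface.mask, dtype=bool)
    lats, lons = np.asarray(surface.lats), np.asarray(surface.lons)
    if n == 0:
        return []
    weights = np.where(mask, values, 0.0)
    if effort_bias is not None:
        weights = weights * np.where(mask, np.asarray(effort_bias, dtype=float), 0.0)
    if np.any(weights < 0):
        raise ValueError("sampling weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("sampling weights sum to zero: no ocean cell has positive weight")
    flat = weights.ravel() / total
    idx = rng.choice(flat.size, size=n, p=flat)
    res_lat = abs(lats[1] - lats[0]) if lats.size > 1 else 1.0
    res_lon = abs(lons[1] - lons[0]) if lons.size > 1 else 1.0
    ii, jj = np.unravel_index(idx, values.shape)
    pts = []
    for i, j in zip(ii, jj):
        pts.append((float(lats[i] + rng.uniform(-0.5, 0.5) * res_lat),
                    float(lons[j] + rng.uniform(-0.5, 0.5) * res_lon)))
    return pts


def make_ecorealms(iso: Isoscape, n_bands: int = 3) -> list[Region]:
    """Partition the grid's outer extent into named latitudinal bands."""
    if n_bands < 1:
        raise ValueError("need at least one band")
    res = iso.resolution
    lat_top = iso.lats[0] + res / 2
    lat_bot = iso.lats[-1] - res / 2
    lon_w = iso.lons[0] - res / 2
    lon_e = iso.lons[-1] + res / 2
    edges = np.linspace(lat_bot, lat_top, n_bands + 1)
    regions = []
    for k in range(n_bands):
        geom = box(lon_w, edges[k], lon_e, edges[k + 1])
        regions.append(Region(f"Band {k + 1}", geom))
    return regions
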