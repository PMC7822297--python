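"""Probability-of-origin surfaces and combined (dual-isotope) origin maps.

For one corrected feather value y and an isoscape with per-cell mean mu_c
and SD sigma_c, the probability of origin at ocean cell c is the normal
density N(y; mu_c, sigma_c) normalized to sum to one over ocean cells.
Per-individual surfaces are averaged into group surfaces, each isotope's
surface is centered and scaled (z-scored over ocean cells), and the two
scaled layers are summed into one combined origin score per cell. Combined
scores are relative: they are interpreted only against quantiles of their
own map, and maps are compared by the Jaccard index of their binarized
top-quantile cell sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import Isoscape

__all__ = [
    "OriginSurface", "origin_surface", "group_surface", "scale_surfaces",
    "combine_isotopes", "quantile_mask", "jaccard_index",
]

#: default analytical uncertainties (one SD, permil) used when the isoscape
#: carries no SD layer
DEFAULT_SIGMA = {"C13": 0.10, "O18": 0.50}

_SD_EPS = 1e-12


@dataclass
class OriginSurface:
    """A per-cell origin score raster on the isoscape's geometry.

    ``stage`` records what the values mean: ``raw_normalized`` (>= 0, sums
    to 1 over ocean), ``scaled`` (z-scored, unbounded) or ``combined``
    (sum of two scaled layers).
    """

    values: np.ndarray
    mask: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    stage: str = "raw_normalized"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.stage == "raw_normalized":
            ov = self.values[self.mask]
            if ov.size and (np.any(ov < 0) or abs(ov.sum() - 1.0) > 1e-9):
                raise ValueError("raw_normalized surface must be >= 0 and sum to 1")

    def same_geometry(self, other) -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.lats, other.lats)
                and np.allclose(self.lons, other.lons)
                and np.array_equal(self.mask, other.mask))

    def ocean_values(self) -> np.ndarray:
        return self.values[self.mask]

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.ocean_values(), q))

    def with_values(self, values, stage, **prov) -> "OriginSurface":
        p = dict(self.provenance)
        p.update(prov)
        return OriginSurface(values, self.mask, self.lats, self.lons, stage, p)


def origin_surface(value_corr: float, iso: Isoscape,
                   sigma_extra: float | None = None,
                   isotope: str | None = None) -> OriginSurface:
    """Normalized probability-of-origin surface for one corrected value.

    Per-cell SD is sqrt(iso.sd^2 + sigma_extra^2); when the isoscape has no
    SD layer and ``sigma_extra`` is not given, the analytical uncertainty
    for ``isotope`` (0.10 permil for C13, 0.50 for O18) is used.
    """
    iso.require_ocean()
    if not np.isfinite(value_corr):
        raise ValueError("feather value must be finite")
    if sigma_extra is None:
        sigma_extra = 0.0 if iso.sd is not None else DEFAULT_SIGMA.get(isotope, 0.0)
    sd_grid = iso.sd_grid()
    base = np.zeros(iso.shape) if sd_grid is None else sd_grid
    sigma = np.sqrt(base ** 2 + float(sigma_extra) ** 2)

    weights = np.zeros(iso.shape)
    ocean = iso.mask
    sig_o = sigma[ocean]
    mu_o = iso.values[ocean]
    if np.all(sig_o <= _SD_EPS):
        exact = np.abs(mu_o - value_corr) <= _SD_EPS
        if not exact.any():
            raise ValueError("degenerate sd: all cell SDs are zero and the value "
                             "matches no cell exactly")
        w = exact.astype(float)
    else:
        if np.any(sig_o <= _SD_EPS):
            raise ValueError("degenerate sd: some (but not all) cell SDs are zero")
        z = (value_corr - mu_o) / sig_o
        w = np.exp(-0.5 * z ** 2) / (sig_o * np.sqrt(2 * np.pi))
    total = w.sum()
    if total <= 0:
        raise ValueError("all origin densities underflowed to zero; "
                         "the value is implausibly far from every cell")
    weights[ocean] = w / total
    return OriginSurface(weights, iso.mask.copy(), iso.lats.copy(), iso.lons.copy(),
                         stage="raw_normalized",
                         provenance={"isotope": isotope, "n_individuals": 1})


def group_surface(members) -> OriginSurface:
    """Cell-wise mean of per-individual raw normalized surfaces."""
    members = list(members)
    if not members:
        raise ValueError("no member surfaces")
    first = members[0]
    for s in members:
        if s.stage != "raw_normalized":
            raise ValueError("group_surface expects raw_normalized members")
        if not first.same_geometry(s):
            raise ValueError("member surfaces differ in geometry")
    values = np.mean([s.values for s in members], axis=0)
    return first.with_values(values, "raw_normalized",
                             n_individuals=len(members))


def scale_surfaces(stack, mode: str = "per_layer"):
    """Center and scale a stack of surfaces over their ocean cells.

    ``per_layer``: each layer is z-scored by its own mean and sample SD.
    ``pooled_sd``: each layer is centered by its own mean but divided by the
    SD pooled across every layer in the stack (one scale per hemisphere
    grouping). A constant layer becomes all zeros with a warning.
    """
    stack = list(stack)
    if not stack:
        raise ValueError("empty stack")
    first = stack[0]
    for s in stack:
        if not first.same_geometry(s):
            raise ValueError("stack surfaces differ in geometry")
    if mode not in ("per_layer", "pooled_sd"):
        raise ValueError(f"unknown mode {mode!r}")
    centered = []
    for s in stack:
        ov = s.ocean_values()
        centered.append(ov - ov.mean())
    if mode == "pooled_sd":
        pooled = np.concatenate(centered)
        denom = [float(np.sqrt((pooled ** 2).sum() / (pooled.size - 1)))] * len(stack)
    else:
        denom = [float(np.std(c, ddof=1)) for c in centered]
    out = []
    for s, c, sd in zip(stack, centered, denom):
        if sd <= _SD_EPS:
            warnings.warn(f"constant layer ({s.provenance}): scaled to all zeros")
            scaled = np.zeros_like(c)
        else:
            scaled = c / sd
        values = np.zeros(s.values.shape)
        values[s.mask] = scaled
        out.append(s.with_values(values, "scaled", scale_mode=mode))
    return out


def combine_isotopes(scaled_c: OriginSurface, scaled_o: OriginSurface) -> OriginSurface:
    """Cell-wise sum of the two scaled single-isotope surfaces."""
    for s in (scaled_c, scaled_o):
        if s.stage != "scaled":
            raise ValueError("combine_isotopes expects scaled surfaces")
    if not scaled_c.same_geometry(scaled_o):
        raise ValueError("surfaces differ in geometry")
    return scaled_c.with_values(scaled_c.values + scaled_o.values, "combined",
                                isotope="combined")


def quantile_mask(surface: OriginSurface, q: float):
    """(threshold, boolean grid) of ocean cells strictly above the empirical
    q-quantile of the surface."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    threshold = surface.quantile(q)
    mask = surface.mask & (surface.values > threshold)
    return threshold, mask


def jaccard_index(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A & B| / |A | B| of two boolean cell sets; 0 (with warning) if both
    are empty."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks differ in shape")
    union = int((mask_a | mask_b).sum())
    if union == 0:
        warnings.warn("both masks empty; Jaccard index defined as 0")
        return 0.0
    return float((mask_a & mask_b).sum() / union)
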