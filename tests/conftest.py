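import numpy as np
import pandas as pd
import pytest

from moultmap import Isoscape, SimConfig


@pytest.fixture
def tiny_iso():
    """3x3 grid, one land cell, simple values."""
    values = np.arange(9, dtype=float).reshape(3, 3) - 22.0
    mask = np.ones((3, 3), dtype=bool)
    mask[1, 1] = False
    return Isoscape(values, lats=[2.5, 1.5, 0.5], lons=[10.5, 11.5, 12.5],
                    mask=mask)


@pytest.fixture
def small_cfg():
    """Compact southern-hemisphere world for fast end-to-end runs."""
    return SimConfig(
        lat_min=-70, lat_max=-30, lon_min=-45, lon_max=5,
        land_boxes=((-40, -30, -5, 5),),
        group_centers=((-55.5, -30.5), (-40.5, -20.5)),
        seed=42,
    )


@pytest.fixture
def zero_noise_cfg(small_cfg):
    """Deterministic generative world: no noise, no year effect, no spread."""
    from dataclasses import replace
    return replace(small_cfg, noise_sd_c=0.0, noise_sd_o=0.0,
                   year_effect_c=0.0, year_effect_o=0.0, group_spread=0.0)


@pytest.fixture
def toy_records():
    """Five hand-written records: 3 clean, 1 missing d18O, 1 ESP outlier."""
    return pd.DataFrame({
        "id": pd.array(["a", "b", "c", "d", "e"], dtype="string"),
        "species": pd.array(["ESP", "ESP", "LSP", "LSP", "ESP"], dtype="string"),
        "year": pd.array(["2018"] * 5, dtype="string"),
        "sex": pd.array(["F", "M", "F", "M", "F"], dtype="string"),
        "d13C_raw": [-19.5, -24.0, -21.0, -20.5, -18.9],
        "d15N": [12.0, 11.5, 13.0, 12.5, 11.9],
        "d18O_raw": [12.6, 11.0, np.nan, 13.1, 12.0],
        "fgr": [2.4] * 5,
        "body_mass": [28.0] * 5,
        "tarsus": [23.0] * 5,
        "wing": [150.0] * 5,
    })
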