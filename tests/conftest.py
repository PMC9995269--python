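import numpy as np
import pytest
import xarray as xr

from rainfor import SynthConfig, generate_bundle
from rainfor.grids import make_grid, cover_loss

START_YEARS = range(2003, 2008)
END_YEARS = range(2013, 2018)


def grid_da(values, resolution=0.05, name="loss", **attrs):
    """Wrap a 2-D array as a lat/lon DataArray on an equator-centred grid."""
    values = np.asarray(values, dtype=float)
    lat, lon = make_grid(*values.shape, resolution)
    attrs.setdefault("resolution", resolution)
    return xr.DataArray(values, dims=("lat", "lon"),
                        coords={"lat": lat, "lon": lon}, name=name, attrs=attrs)


def cube_da(values, year0=2003, resolution=0.05, **attrs):
    """Wrap a (time, lat, lon) array as a monthly precipitation cube."""
    import pandas as pd

    values = np.asarray(values, dtype=float)
    lat, lon = make_grid(values.shape[1], values.shape[2], resolution)
    time = pd.date_range(f"{year0}-01-01", periods=values.shape[0], freq="MS")
    attrs.setdefault("units", "mm/month")
    attrs.setdefault("resolution", resolution)
    return xr.DataArray(values, dims=("time", "lat", "lon"),
                        coords={"time": time, "lat": lat, "lon": lon},
                        name="precip", attrs=attrs)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Deterministic world: linear beta = -0.25, no noise, no ENSO."""
    cfg = SynthConfig(shape=(24, 24), sigma=0.0, beta=-0.25, n_clusters=6, seed=7)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default study conditions at a reduced grid for unit tests."""
    cfg = SynthConfig(shape=(48, 48), sigma=10.0, beta=-0.25, seed=11)
    return generate_bundle(cfg)


@pytest.fixture()
def window_loss():
    """Loss differenced over the same 5-yr windows as the precipitation."""

    def _make(bundle):
        return cover_loss(bundle.cover, START_YEARS, END_YEARS)

    return _make
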