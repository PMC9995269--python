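"""Multi-scale grid operations for cover/loss fields and precipitation cubes.

Conventions used throughout the package:

* cover / loss grids are 2-D :class:`xarray.DataArray` objects with dims
  ``("lat", "lon")``, cell-centre coordinates in degrees on a regular grid,
  values in percent (cover) or percentage points (loss), NaN for missing;
* precipitation cubes are 3-D DataArrays with dims ``("time", "lat", "lon")``,
  a complete monthly time axis and values in mm/month;
* region / biome masks are boolean 2-D DataArrays aligned to their grid.

Only coarsening is supported: analysis scales are at or below the native
resolution of the inputs.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable

import numpy as np
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "make_grid",
    "cell_areas",
    "aggregate_loss",
    "regrid_precip",
    "period_mean",
    "cover_loss",
]


def make_grid(
    ny: int, nx: int, resolution: float, lat0: float | None = None, lon0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Return (lat, lon) cell-centre coordinate vectors for a regular grid.

    By default the grid is centred on the equator / prime meridian, which is
    a reasonable stand-in for a tropical analysis domain.
    """
    if ny < 1 or nx < 1:
        raise ValueError(f"grid shape must be positive, got ({ny}, {nx})")
    if lat0 is None:
        lat0 = -resolution * (ny - 1) / 2.0
    if lon0 is None:
        lon0 = -resolution * (nx - 1) / 2.0
    lat = lat0 + resolution * np.arange(ny)
    lon = lon0 + resolution * np.arange(nx)
    return lat, lon


def cell_areas(lat: np.ndarray, resolution: float) -> np.ndarray:
    """Exact spherical area of each latitude band cell (unit sphere, per cell).

    area = Δlon × (sin(lat + Δlat/2) − sin(lat − Δlat/2)); using the exact
    band area (rather than cos-latitude × Δlat) makes area-weighted
    aggregation conserve total lost forest area to machine precision.
    """
    lat = np.asarray(lat, dtype=float)
    half = np.deg2rad(resolution) / 2.0
    phi = np.deg2rad(lat)
    return np.deg2rad(resolution) * (np.sin(phi + half) - np.sin(phi - half))


def _resolution_of(da: xr.DataArray) -> float:
    lat = da["lat"].values
    if lat.size < 2:
        return float(da.attrs.get("resolution", np.nan))
    steps = np.diff(lat)
    if not np.allclose(steps, steps[0]):
        raise ValueError("grid latitudes are not regularly spaced")
    return float(abs(steps[0]))


def aggregate_loss(fine: xr.DataArray, factor: int, missing_frac: float = 0.5) -> xr.DataArray:
    """Aggregate a fractional loss (or cover) grid to a coarser resolution.

    Each coarse cell is the area-weighted mean of the ``factor × factor``
    block of fine cells it contains — equivalently, the total lost forest
    area in the block divided by the block area, expressed in percent.
    Missing fine cells are excluded from the weights; a coarse cell is
    missing when more than ``missing_frac`` of its block area is missing.
    Blocks that do not fit (edge partials) are dropped with a warning.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"aggregation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return fine.copy()

    vals = np.asarray(fine.values, dtype=float)
    ny, nx = vals.shape
    nyc, nxc = ny // factor, nx // factor
    if nyc < 1 or nxc < 1:
        raise ValueError(f"factor {factor} larger than grid {vals.shape}")
    if ny % factor or nx % factor:
        logger.warning(
            "aggregate_loss: dropping %d row(s) and %d column(s) of edge-partial blocks",
            ny - nyc * factor,
            nx - nxc * factor,
        )
        vals = vals[: nyc * factor, : nxc * factor]

    res = _resolution_of(fine)
    lat = fine["lat"].values[: nyc * factor]
    lon = fine["lon"].values[: nxc * factor]
    w = np.broadcast_to(cell_areas(lat, res)[:, None], vals.shape)

    blocks = vals.reshape(nyc, factor, nxc, factor)
    wblocks = w.reshape(nyc, factor, nxc, factor)
    valid = np.isfinite(blocks)
    wsum = np.where(valid, wblocks, 0.0).sum(axis=(1, 3))
    vsum = np.where(valid, wblocks * blocks, 0.0).sum(axis=(1, 3))
    wtot = wblocks.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        coarse = vsum / wsum
    coarse[(wtot - wsum) > missing_frac * wtot] = np.nan
    coarse[wsum == 0] = np.nan

    lat_c = lat.reshape(nyc, factor).mean(axis=1)
    lon_c = lon.reshape(nxc, factor).mean(axis=1)
    out = xr.DataArray(
        coarse,
        dims=("lat", "lon"),
        coords={"lat": lat_c, "lon": lon_c},
        name=fine.name,
        attrs=dict(fine.attrs),
    )
    out.attrs["resolution"] = res * factor
    return out


def regrid_precip(
    cube: xr.DataArray,
    target_lat: np.ndarray,
    target_lon: np.ndarray,
    method: str = "bilinear",
) -> xr.DataArray:
    """Regrid a monthly precipitation cube onto target cell centres.

    ``bilinear`` (default) interpolates cell-centre values, treating months
    independently; it preserves constants and reproduces planar fields
    exactly. ``conservative`` is an exact area-weighted block mean and
    requires the target to be an integer-factor coarsening aligned with the
    source grid.
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)
    src_lat = cube["lat"].values
    src_lon = cube["lon"].values
    if target_lat.min() < src_lat.min() - 1e-9 or target_lat.max() > src_lat.max() + 1e-9 or (
        target_lon.min() < src_lon.min() - 1e-9 or target_lon.max() > src_lon.max() + 1e-9
    ):
        raise ValueError("target grid does not overlap the cube's domain")

    if method == "bilinear":
        out = cube.interp(lat=target_lat, lon=target_lon, method="linear")
    elif method == "conservative":
        ratio = (target_lat[1] - target_lat[0]) / (src_lat[1] - src_lat[0])
        factor = int(round(ratio))
        if not np.isclose(ratio, factor) or factor < 1:
            raise ValueError("conservative regridding requires an aligned integer coarsening")
        frames = [aggregate_loss(cube.isel(time=i), factor) for i in range(cube.sizes["time"])]
        out = xr.concat(frames, dim=cube["time"])
        if not (
            np.allclose(out["lat"].values, target_lat) and np.allclose(out["lon"].values, target_lon)
        ):
            raise ValueError("conservative regridding target is not aligned with the source grid")
    else:
        raise ValueError(f"unknown regridding method: {method!r}")

    out = out.assign_attrs(dict(cube.attrs))
    if target_lat.size > 1:
        out.attrs["resolution"] = float(abs(target_lat[1] - target_lat[0]))
    return out


def period_mean(
    cube: xr.DataArray,
    years: Iterable[int],
    month_sel: np.ndarray | None = None,
) -> xr.DataArray:
    """Per-pixel mean precipitation (mm/month) over all months of the listed years.

    A pixel is missing if any contributing month is missing, which avoids
    seasonally biased means. ``month_sel`` optionally restricts the mean to a
    per-pixel set of calendar months: a boolean array of shape
    ``(12, nlat, nlon)`` where entry ``[m-1, i, j]`` selects month ``m`` at
    pixel ``(i, j)`` (used for the seasonal analysis).
    """
    years = sorted(set(int(y) for y in years))
    cube_years = np.unique(cube["time"].dt.year.values)
    missing = [y for y in years if y not in cube_years]
    if missing:
        raise ValueError(f"requested years {missing} outside cube span {cube_years.min()}-{cube_years.max()}")

    sub = cube.sel(time=cube["time"].dt.year.isin(years))
    if month_sel is None:
        return sub.mean("time", skipna=False)

    month_sel = np.asarray(month_sel, dtype=bool)
    if month_sel.shape != (12, cube.sizes["lat"], cube.sizes["lon"]):
        raise ValueError("month_sel must have shape (12, nlat, nlon)")
    months = sub["time"].dt.month.values  # 1..12
    w = month_sel[months - 1].astype(float)  # (ntime, nlat, nlon)
    vals = sub.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        num = np.where(w > 0, vals * w, 0.0).sum(axis=0)  # NaN in any *selected* month propagates
        den = w.sum(axis=0)
        mean = np.where(den > 0, num / den, np.nan)
    return xr.DataArray(
        mean,
        dims=("lat", "lon"),
        coords={"lat": cube["lat"], "lon": cube["lon"]},
        attrs=dict(cube.attrs),
    )


def cover_loss(
    cover: xr.DataArray,
    start_years: Iterable[int] | None = None,
    end_years: Iterable[int] | None = None,
) -> xr.DataArray:
    """Forest-cover loss (pp) between two multi-annual windows.

    Loss is the difference of the mean cover over the start years and over
    the end years of the analysis period (clipped at 0). Using the same
    multi-annual windows as the precipitation differencing keeps the
    ΔP/ΔF ratio an unattenuated estimate of the underlying sensitivity;
    differencing single end-point years instead would mismatch the
    precipitation windows and shrink the ratio by a known factor. With
    ``None`` the first/last single year is used.

    ``cover`` has dims ``(year, lat, lon)`` with an integer ``year``
    coordinate.
    """
    years = cover["year"].values
    start_years = [int(years[0])] if start_years is None else sorted(set(map(int, start_years)))
    end_years = [int(years[-1])] if end_years is None else sorted(set(map(int, end_years)))
    for y in (*start_years, *end_years):
        if y not in years:
            raise ValueError(f"year {y} outside cover span {years.min()}-{years.max()}")
    start = cover.sel(year=start_years).mean("year", skipna=False)
    end = cover.sel(year=end_years).mean("year", skipna=False)
    loss = (start - end).clip(min=0.0)
    loss.attrs = dict(cover.attrs)
    loss.attrs["units"] = "percentage points"
    loss.name = "loss"
    return loss
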