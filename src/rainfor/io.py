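"""Readers, writers, configuration and the end-to-end pipeline driver.

All NetCDF I/O goes through xarray's ``scipy`` engine (NetCDF3 classic), so
files written here are readable anywhere. Precipitation units are
normalised to mm/month on read: ``mm/day`` (and aliases) are converted with
each month's actual day count. Only standard-calendar monthly time axes are
accepted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .grids import aggregate_loss, regrid_precip, make_grid, cover_loss
from .pairing import WindowSpec, find_pairs, pair_delta_p, climate_similarity_filter
from .sensitivity import (
    estimate, season_map, seasonal_estimate, binned_response,
    estimates_to_frame, DEFAULT_BIN_EDGES,
)
from .projection import project_linear, project_capped, project_nonlinear, regional_summary

logger = logging.getLogger(__name__)

__all__ = [
    "read_precip_netcdf", "read_cover", "read_mask", "write_netcdf",
    "write_pairs", "write_estimates", "PipelineConfig", "run_pipeline",
]

_MM_PER_MONTH = {"mm/month", "mm month-1", "mm.month-1", "millimetres per month"}
_MM_PER_DAY = {"mm/day", "mm day-1", "mm.day-1", "millimetres per day"}


def write_netcdf(ds: xr.Dataset | xr.DataArray, path: str | Path) -> None:
    """Write a dataset as NetCDF3 classic (portable, text-tool friendly)."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    encoding = {}
    if "time" in ds.coords:
        encoding["time"] = {"dtype": "float64"}
    ds.to_netcdf(path, engine="scipy", encoding=encoding)


def _open(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy")


def read_precip_netcdf(path: str | Path, var: str | None = None) -> xr.DataArray:
    """Read a monthly precipitation cube, normalising units to mm/month.

    Requires CF-style ``time``, ``lat``, ``lon`` coordinates and a ``units``
    attribute of mm/month or mm/day (converted via days in month). Unknown
    units are a hard error, never a silent pass-through.
    """
    ds = _open(path)
    if var is None:
        candidates = [v for v in ds.data_vars if set(ds[v].dims) >= {"time", "lat", "lon"}]
        if len(candidates) != 1:
            raise ValueError(f"cannot identify the precipitation variable in {path}: {list(ds.data_vars)}")
        var = candidates[0]
    da = ds[var]
    for coord in ("time", "lat", "lon"):
        if coord not in da.coords:
            raise ValueError(f"precipitation file {path} is missing coordinate {coord!r}")
    units = str(da.attrs.get("units", "")).strip().lower()
    if units in _MM_PER_MONTH:
        out = da
    elif units in _MM_PER_DAY:
        days = da["time"].dt.days_in_month
        out = da * days
        out.attrs.update(da.attrs)
        logger.info("read_precip_netcdf: converted %s from mm/day to mm/month", path)
    else:
        raise ValueError(f"unrecognised precipitation units {units!r} in {path}")
    out.attrs["units"] = "mm/month"
    return out.transpose("time", "lat", "lon")


def read_cover(path: str | Path, var: str = "cover") -> xr.DataArray:
    ds = _open(path)
    return ds[var]


def read_mask(path: str | Path, var: str = "mask") -> xr.DataArray:
    ds = _open(path)
    return ds[var].astype(bool)


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, index=False)


def write_estimates(estimates, path: str | Path) -> None:
    """Estimates as CSV (``.csv``) or JSON (anything else)."""
    frame = estimates_to_frame(estimates)
    path = Path(path)
    if path.suffix == ".csv":
        frame.to_csv(path, index=False)
    else:
        path.write_text(frame.to_json(orient="records", indent=2))


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serialisable)."""

    cover_path: str = ""
    precip_path: str = ""
    mask_path: str = ""
    future_loss_path: str = ""
    out_dir: str = "rainfor_out"
    factors: tuple[int, ...] = (1, 2)
    window_size: int = 3
    compositing: str = "mean"
    min_excess: float = 0.1
    windows: dict = field(default_factory=lambda: {
        "5yr": ([2003, 2004, 2005, 2006, 2007], [2013, 2014, 2015, 2016, 2017]),
    })
    similarity_threshold: float | None = None
    seasonal: bool = False
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    projection_mode: str = "linear"  # linear | capped | nonlinear
    cap_pp: float = 30.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.factors:
            raise ValueError("config lists no analysis scales (factors)")
        if sorted(self.factors) != list(self.factors):
            raise ValueError("factors must be sorted ascending")
        if not self.windows:
            raise ValueError("config lists no analysis windows")
        for p in (self.cover_path, self.precip_path, self.mask_path):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis: aggregate → regrid → pair → estimate → project.

    Writes pair CSVs, estimate tables, projection NetCDFs and a manifest
    under ``config.out_dir``; returns the manifest dict. Deterministic for a
    fixed config and seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "valid": False,
    }
    stage = "read"
    try:
        cover = read_cover(config.cover_path)
        precip = read_precip_netcdf(config.precip_path)
        mask = read_mask(config.mask_path)
        manifest["stages"]["read"] = {"n_in_mask": int(mask.values.sum())}

        window = WindowSpec(size=config.window_size, compositing=config.compositing)
        all_estimates = []
        pairs_by_factor = {}
        for factor in config.factors:
            stage = f"aggregate(x{factor})"
            mask_f = (
                aggregate_loss(mask.astype(float), factor) > 0.5 if factor > 1 else mask
            )
            stage = f"regrid(x{factor})"
            cube = (
                regrid_precip(precip, mask_f["lat"].values, mask_f["lon"].values)
                if factor > 1 else precip
            )
            counts = {"n_in_mask": int(np.asarray(mask_f.values, bool).sum())}
            for label, (start_years, end_years) in config.windows.items():
                # loss differenced over the same multi-annual windows as precipitation
                stage = f"pairs(x{factor},{label})"
                loss = cover_loss(cover, start_years, end_years)
                if factor > 1:
                    loss = aggregate_loss(loss, factor)
                pairs = find_pairs(loss, mask_f, window, config.min_excess)
                counts[f"n_deforested_{label}"] = pairs.n_pairs
                stage = f"estimate(x{factor},{label})"
                df = pair_delta_p(pairs, cube, start_years, end_years)
                if config.similarity_threshold is not None:
                    df = climate_similarity_filter(df, config.similarity_threshold)
                write_pairs(df, out / f"pairs_x{factor}_{label}.csv")
                counts[f"n_pairs_{label}"] = len(df)
                if len(df):
                    est = estimate(df, seed=config.seed, label=f"x{factor}:{label}")
                    all_estimates.append(est)
                    pairs_by_factor[(factor, label)] = df
            if config.seasonal:
                stage = f"seasonal(x{factor})"
                smap = season_map(cube)
                label, (sy, ey) = next(iter(config.windows.items()))
                loss = cover_loss(cover, sy, ey)
                if factor > 1:
                    loss = aggregate_loss(loss, factor)
                pairs = find_pairs(loss, mask_f, window, config.min_excess)
                seas = seasonal_estimate(pairs, cube, smap, sy, ey,
                                         filter_threshold=config.similarity_threshold,
                                         seed=config.seed, label=f"x{factor}:{label}")
                all_estimates.extend(seas.values())
            manifest["stages"][f"x{factor}"] = counts

        stage = "write-estimates"
        write_estimates(all_estimates, out / "estimates.csv")
        write_estimates(all_estimates, out / "estimates.json")

        if config.future_loss_path:
            stage = "project"
            future = _open(config.future_loss_path)["loss"]
            # sensitivity from the coarsest scale's first window
            factor, label = max(config.factors), next(iter(config.windows))
            df = pairs_by_factor.get((factor, label))
            if df is None or not len(df):
                raise RuntimeError("no pairs available to derive a projection sensitivity")
            s = estimate(df, seed=config.seed)
            if config.projection_mode == "linear":
                field_ds = project_linear(future, s)
            elif config.projection_mode == "capped":
                field_ds = project_capped(future, s, config.cap_pp)
            elif config.projection_mode == "nonlinear":
                field_ds = project_nonlinear(future, binned_response(df, config.bin_edges))
            else:
                raise ValueError(f"unknown projection mode {config.projection_mode!r}")
            write_netcdf(field_ds, out / "projection.nc")
            baseline = precip.mean("time", skipna=False)
            if field_ds["dp"].shape == baseline.shape:
                summary = regional_summary(field_ds, {"domain": xr.ones_like(future, dtype=bool)},
                                           baseline)
                summary.to_csv(out / "projection_regional.csv", index=False)
        manifest["valid"] = True
    except Exception as exc:
        manifest["error"] = f"stage {stage}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
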