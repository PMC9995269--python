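"""Synthetic gridded data with a known deforestation–precipitation sensitivity.

The generator emulates the four inputs of the observational pipeline —
annual fractional forest-cover grids, an evergreen-broadleaf biome mask,
monthly precipitation cubes, and a future forest-loss scenario — with a
ground-truth precipitation response to local forest loss injected, so that
every downstream stage can be verified by parameter recovery.

The generative model is deliberately simple (it is a test fixture, not a
climate model):

* cover: a near-uniform baseline minus spatially clustered loss (a
  loss-only process). Loss patches are sharp at the pixel scale (Gaussian
  bumps with sub-pixel decay) with magnitudes spread across [0, max_loss],
  emulating the wide spectrum of local canopy-loss contrasts that
  fine-resolution forest-change data exhibit; each patch is cleared as a
  linear ramp over a configurable interior period of the record (default
  2008–2012), so the full contrast is expressed between typical early and
  late analysis windows;
* precipitation at pixel *i*, year *y*, month *m*:

  ``P = clim(i, m) + noise(i, y) + enso(y) + response(beta, loss(i, y))``

  where ``clim`` is a per-pixel sinusoidal seasonal cycle, ``noise`` is iid
  Gaussian per pixel-year applied to all 12 months equally (keeping each
  pixel's seasonal ranking stable), ``enso`` is an additive spatially
  uniform anomaly in El Niño years, and ``response`` is the injected effect:
  linear ``beta * L`` or saturating ``beta * H * L / (H + L)`` (initial
  slope ``beta``, half-saturation ``H``). Precipitation is floored at zero.

All randomness derives from a single seed; identical configurations produce
bit-identical bundles, and the noise draws do not depend on ``beta``, so a
``beta = 0`` run with the same seed is an exact counterfactual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import make_grid

__all__ = ["SynthConfig", "SynthBundle", "generate_cover_history", "generate_precip",
           "generate_future_loss", "generate_bundle"]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic world.

    Percentages / percentage points are on the 0–100 scale; precipitation
    quantities are mm/month; ``beta`` is mm/month per percentage point of
    forest loss (negative for a drying response).
    """

    shape: tuple[int, int] = (64, 64)
    resolution: float = 0.05
    factors: tuple[int, ...] = (1, 2)
    year_start: int = 2003
    year_end: int = 2017
    # precipitation climatology and variability
    precip_mean: float = 100.0
    seasonal_amplitude: float = 40.0
    sigma: float = 10.0
    noise_per_month: bool = True
    # forest loss pattern
    baseline_cover: float = 90.0
    cover_noise: float = 3.0
    n_clusters: int = 150
    max_loss: float = 50.0
    decay: float = 0.6
    cluster_height_min: float = 0.1
    loss_period: tuple[int, int] | None = (2008, 2012)
    mask_fraction: float = 1.0
    # injected response
    beta: float = -0.25
    response: str = "linear"  # "linear" | "saturating"
    half_saturation: float = 30.0
    response_months: str = "all"  # "all" | "dry": confine the effect to each pixel's 3 driest months
    # ENSO
    elnino_years: tuple[int, ...] = ()
    elnino_anomaly: float = 0.0
    elnino_beta_multiplier: float = 1.0
    # future scenario
    future_mode: str = "clustered"  # "clustered" | "uniform"
    future_uniform_loss: float = 40.0
    future_max_loss: float = 60.0
    future_n_clusters: int = 25
    future_decay: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.shape
        if ny < 1 or nx < 1:
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if not 0.0 <= self.max_loss <= 100.0:
            raise ValueError("max_loss must be in [0, 100] percentage points")
        if not 0.0 <= self.future_max_loss <= 100.0 or not 0.0 <= self.future_uniform_loss <= 100.0:
            raise ValueError("future loss must be in [0, 100] percentage points")
        if not 0.0 <= self.baseline_cover <= 100.0:
            raise ValueError("baseline_cover must be in [0, 100] percent")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.year_end - self.year_start + 1 < 6:
            raise ValueError("need at least 6 years so that two 3-yr windows fit")
        if self.response not in ("linear", "saturating"):
            raise ValueError(f"unknown response form {self.response!r}")
        if self.response_months not in ("all", "dry"):
            raise ValueError(f"unknown response_months {self.response_months!r}")
        if not 0.0 < self.cluster_height_min <= 1.0:
            raise ValueError("cluster_height_min must be in (0, 1]")
        if self.loss_period is not None:
            y0, y1 = self.loss_period
            if not (self.year_start <= y0 <= y1 <= self.year_end):
                raise ValueError("loss_period must lie within the simulated years")
        if not 0.0 < self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must be in (0, 1]")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def _streams(self) -> list[np.random.Generator]:
        # independent child streams: 0 = cover, 1 = precip, 2 = future scenario
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(3)]


@dataclass
class SynthBundle:
    """All synthetic inputs plus the ground truth used to generate them."""

    cover: xr.DataArray          # (year, lat, lon), percent canopy cover
    mask: xr.DataArray           # (lat, lon), bool biome mask
    precip: xr.DataArray         # (time, lat, lon), mm/month
    future_loss: xr.DataArray    # (lat, lon), pp loss vs baseline
    truth: dict = field(default_factory=dict)
    config: SynthConfig | None = None

    def to_dir(self, outdir: str | Path) -> None:
        from . import io  # local import to avoid a cycle

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_netcdf(self.cover.to_dataset(name="cover"), outdir / "cover.nc")
        io.write_netcdf(self.mask.astype("int8").to_dataset(name="mask"), outdir / "mask.nc")
        io.write_netcdf(self.precip.to_dataset(name="precip"), outdir / "precip.nc")
        io.write_netcdf(self.future_loss.to_dataset(name="loss"), outdir / "future_loss.nc")
        truth = dict(self.truth)
        if self.config is not None:
            truth["config"] = asdict(self.config)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, default=str))


def _cluster_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_clusters: int,
    peak: float,
    decay: float,
    height_min: float = 0.1,
) -> np.ndarray:
    """Spatially clustered field: pointwise max over Gaussian bumps.

    The first bump has height exactly ``peak``; the rest draw heights
    uniformly from ``[height_min, 1] x peak``, so patch magnitudes span the
    whole range up to ``peak`` (the observed canopy-change spectrum, rather
    than a single characteristic loss). Combining patches with a maximum
    (not a sum) keeps the field bounded by ``peak`` while guaranteeing the
    first seed pixel attains it exactly.
    """
    ny, nx = shape
    out = np.zeros(shape)
    if n_clusters == 0 or peak == 0:
        return out
    rows = rng.integers(0, ny, size=n_clusters)
    cols = rng.integers(0, nx, size=n_clusters)
    heights = np.full(n_clusters, float(peak))
    if n_clusters > 1:
        heights[1:] = peak * rng.uniform(height_min, 1.0, n_clusters - 1)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for r, c, h in zip(rows, cols, heights):
        d2 = (yy - r) ** 2 + (xx - c) ** 2
        np.maximum(out, h * np.exp(-d2 / (2.0 * decay**2)), out=out)
    return out


def _biome_mask(config: SynthConfig) -> np.ndarray:
    ny, nx = config.shape
    mask = np.zeros((ny, nx), dtype=bool)
    f = np.sqrt(config.mask_fraction)
    my = int(round(ny * (1 - f) / 2))
    mx = int(round(nx * (1 - f) / 2))
    mask[my : ny - my, mx : nx - mx] = True
    return mask


def generate_cover_history(config: SynthConfig) -> tuple[xr.DataArray, xr.DataArray]:
    """Annual fractional cover grids (loss-only) plus the biome mask.

    Loss is clustered around randomly placed seed points and accumulates as
    a linear ramp over ``config.loss_period`` (by default the interior years
    of the record, so early and late multi-annual windows bracket the full
    contrast; ``None`` ramps over the whole span). Per-pixel total loss is
    capped at the pixel's baseline cover so cover stays in [0, 100].
    """
    rng_cover = config._streams()[0]
    ny, nx = config.shape
    lat, lon = make_grid(ny, nx, config.resolution)

    base = config.baseline_cover + config.cover_noise * rng_cover.standard_normal((ny, nx))
    base = np.clip(base, 0.0, 100.0)
    total_loss = _cluster_field(rng_cover, config.shape, config.n_clusters,
                                config.max_loss, config.decay, config.cluster_height_min)
    total_loss = np.minimum(total_loss, base)

    years = config.years
    y0, y1 = config.loss_period or (int(years[0]) + 1, int(years[-1]))
    ramp = np.clip((years - (y0 - 1)) / (y1 - (y0 - 1)), 0.0, 1.0)
    cover = base[None, :, :] - ramp[:, None, None] * total_loss[None, :, :]

    cover_da = xr.DataArray(
        cover,
        dims=("year", "lat", "lon"),
        coords={"year": years, "lat": lat, "lon": lon},
        name="cover",
        attrs={"units": "percent", "resolution": config.resolution},
    )
    mask_da = xr.DataArray(
        _biome_mask(config),
        dims=("lat", "lon"),
        coords={"lat": lat, "lon": lon},
        name="mask",
        attrs={"long_name": "evergreen broadleaf biome mask (synthetic)"},
    )
    return cover_da, mask_da


def _climatology(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel sinusoidal monthly climatology, shape (12, ny, nx)."""
    ny, nx = config.shape
    phase = rng.integers(0, 12, size=(ny, nx))
    months = np.arange(12)
    clim = config.precip_mean + config.seasonal_amplitude * np.cos(
        2 * np.pi * (months[:, None, None] - phase[None, :, :]) / 12.0
    )
    return clim


def generate_precip(config: SynthConfig, cover: xr.DataArray) -> xr.DataArray:
    """Monthly precipitation cube with the configured response to forest loss."""
    if cover.sizes["lat"] != config.shape[0] or cover.sizes["lon"] != config.shape[1]:
        raise ValueError("cover grid does not match the configured shape")
    rng = config._streams()[1]
    ny, nx = config.shape
    years = config.years
    n_years = years.size

    clim = _climatology(config, rng)  # (12, ny, nx)
    if config.noise_per_month:
        noise = config.sigma * rng.standard_normal((n_years, 12, ny, nx))
    else:
        noise = config.sigma * rng.standard_normal((n_years, 1, ny, nx))
        noise = np.broadcast_to(noise, (n_years, 12, ny, nx))

    loss_pp = np.clip(cover.isel(year=0).values[None, :, :] - cover.values, 0.0, None)  # (year, ny, nx)
    if config.response == "linear":
        resp = config.beta * loss_pp
    else:
        h = config.half_saturation
        resp = config.beta * h * loss_pp / (h + loss_pp)

    is_nino = np.isin(years, np.asarray(config.elnino_years))
    enso = np.where(is_nino, config.elnino_anomaly, 0.0)  # (year,)
    beta_scale = np.where(is_nino, config.elnino_beta_multiplier, 1.0)

    p = (
        clim[None, :, :, :]
        + noise
        + enso[:, None, None, None]
        + (resp * beta_scale[:, None, None])[:, None, :, :]
    )
    if config.response_months == "dry":
        # confine the injected effect to each pixel's 3 climatologically driest months
        order = np.argsort(clim, axis=0, kind="stable")
        dry = np.zeros((12, ny, nx), dtype=bool)
        np.put_along_axis(dry, order[:3], True, axis=0)
        p = (
            clim[None, :, :, :]
            + noise
            + enso[:, None, None, None]
            + (resp * beta_scale[:, None, None])[:, None, :, :] * dry[None, :, :, :]
        )
    p = np.clip(p, 0.0, None).reshape(n_years * 12, ny, nx)

    time = pd.date_range(f"{config.year_start}-01-01", periods=n_years * 12, freq="MS")
    return xr.DataArray(
        p,
        dims=("time", "lat", "lon"),
        coords={"time": time, "lat": cover["lat"], "lon": cover["lon"]},
        name="precip",
        attrs={"units": "mm/month", "category": "satellite", "resolution": config.resolution},
    )


def generate_future_loss(config: SynthConfig) -> xr.DataArray:
    """Projected per-pixel forest-cover loss (pp) relative to a scenario baseline."""
    rng = config._streams()[2]
    ny, nx = config.shape
    lat, lon = make_grid(ny, nx, config.resolution)
    if config.future_mode == "uniform":
        vals = np.full((ny, nx), config.future_uniform_loss)
    elif config.future_mode == "clustered":
        vals = _cluster_field(
            rng, config.shape, config.future_n_clusters, config.future_max_loss,
            config.future_decay, config.cluster_height_min
        )
    else:
        raise ValueError(f"unknown future_mode {config.future_mode!r}")
    return xr.DataArray(
        vals,
        dims=("lat", "lon"),
        coords={"lat": lat, "lon": lon},
        name="loss",
        attrs={"units": "percentage points", "resolution": config.resolution},
    )


def generate_bundle(config: SynthConfig) -> SynthBundle:
    """Generate the full synthetic world: cover history, mask, precipitation, scenario."""
    cover, mask = generate_cover_history(config)
    precip = generate_precip(config, cover)
    future = generate_future_loss(config)
    truth = {
        "beta": config.beta,
        "response": config.response,
        "half_saturation": config.half_saturation,
        "elnino_beta_multiplier": config.elnino_beta_multiplier,
        "elnino_years": list(config.elnino_years),
    }
    return SynthBundle(cover=cover, mask=mask, precip=precip, future_loss=future,
                       truth=truth, config=config)
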