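"""Moving-window nearest-neighbour pairing of deforested pixels with local controls.

Each in-biome pixel is compared with its immediate window neighbours
(3×3 by default, 5×5 supported). Neighbours with strictly less forest loss
than the centre form the pixel's control; the pixel qualifies as a
"deforested pixel" when its loss exceeds the control's by at least 0.1
percentage points. Differencing the two pixels' precipitation changes
removes any signal shared across the window — trends, ENSO anomalies,
dataset biases — leaving the local response to the local loss contrast.

The control is composited as the unweighted mean over all eligible
neighbours by default (lowest-variance local counterfactual); a
minimum-loss single-neighbour variant is available via
``WindowSpec(compositing="min")``. Windows truncate at the domain edges so
border pixels are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grids import period_mean

logger = logging.getLogger(__name__)

__all__ = ["WindowSpec", "PairSet", "find_pairs", "pair_delta_p", "climate_similarity_filter"]

#: minimum excess forest loss (pp) for a pixel to count as deforested
MIN_EXCESS_PP = 0.1


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry and control-compositing rule."""

    size: int = 3
    compositing: str = "mean"  # "mean" | "min" (single minimum-loss neighbour)

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"window size must be odd and >= 3, got {self.size}")
        if self.compositing not in ("mean", "min"):
            raise ValueError(f"unknown compositing rule {self.compositing!r}")

    @property
    def offsets(self) -> list[tuple[int, int]]:
        r = self.size // 2
        return [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1) if (dy, dx) != (0, 0)]


def _shift(a: np.ndarray, dy: int, dx: int, fill: float = np.nan) -> np.ndarray:
    """out[y, x] = a[y + dy, x + dx], padded with ``fill`` outside the domain."""
    ny, nx = a.shape
    out = np.full_like(a, fill, dtype=a.dtype if a.dtype != bool else bool)
    ys = slice(max(0, -dy), ny - max(0, dy))
    xs = slice(max(0, -dx), nx - max(0, dx))
    ysrc = slice(max(0, dy), ny - max(0, -dy))
    xsrc = slice(max(0, dx), nx - max(0, -dx))
    out[ys, xs] = a[ysrc, xsrc]
    return out


def _stack_neighbours(a: np.ndarray, offsets: list[tuple[int, int]], fill: float = np.nan) -> np.ndarray:
    return np.stack([_shift(a, dy, dx, fill) for dy, dx in offsets])


@dataclass
class PairSet:
    """Vectorised pair structure: one entry per grid pixel.

    ``eligible[k, i, j]`` marks neighbour offset ``k`` of pixel ``(i, j)`` as
    part of that pixel's control (in-mask, non-missing, strictly lower loss);
    ``is_pair`` marks the pixels that qualify as deforested.
    """

    window: WindowSpec
    lat: np.ndarray
    lon: np.ndarray
    loss: np.ndarray           # (ny, nx) centre pp loss
    eligible: np.ndarray       # (K, ny, nx) bool
    control_loss: np.ndarray   # (ny, nx)
    delta_f: np.ndarray        # (ny, nx) centre − control loss
    is_pair: np.ndarray        # (ny, nx) bool
    min_excess: float = MIN_EXCESS_PP
    scale: float = field(default=np.nan)

    @property
    def n_pairs(self) -> int:
        return int(self.is_pair.sum())


def _composite(
    values: np.ndarray, eligible: np.ndarray, neigh_loss: np.ndarray, rule: str
) -> np.ndarray:
    """Composite neighbour ``values`` over the eligible set per the rule."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if rule == "mean":
            num = np.where(eligible, values, 0.0).sum(axis=0)
            den = eligible.sum(axis=0)
            return np.where(den > 0, num / den, np.nan)
        # "min": the single eligible neighbour with the least forest loss
        masked = np.where(eligible, neigh_loss, np.inf)
        k = masked.argmin(axis=0)
        out = np.take_along_axis(values, k[None], axis=0)[0]
        return np.where(eligible.any(axis=0), out, np.nan)


def find_pairs(
    loss: xr.DataArray,
    mask: xr.DataArray,
    window: WindowSpec = WindowSpec(),
    min_excess: float = MIN_EXCESS_PP,
) -> PairSet:
    """Identify deforested pixels and their window-derived controls.

    For every in-mask pixel the eligible neighbours are the in-mask,
    non-missing window cells with strictly less loss (a tie carries no
    treatment contrast). The pixel is a deforested pixel iff
    ``centre loss − mean(eligible losses) >= min_excess``. Every pixel is
    evaluated independently; a deforested pixel may also serve inside
    another pixel's control.
    """
    if loss.shape != mask.shape:
        raise ValueError("loss and mask must be on the same grid")
    mask_arr = np.asarray(mask.values, dtype=bool)
    if not mask_arr.any():
        raise ValueError("mask is empty")
    ny, nx = mask_arr.shape
    if window.size > ny or window.size > nx:
        raise ValueError(f"window {window.size} larger than grid {(ny, nx)}")

    vals = np.asarray(loss.values, dtype=float)
    centre_ok = mask_arr & np.isfinite(vals)
    offsets = window.offsets
    neigh = _stack_neighbours(vals, offsets)
    neigh_ok = _stack_neighbours(centre_ok, offsets, fill=False)
    with np.errstate(invalid="ignore"):
        eligible = neigh_ok & (neigh < vals[None]) & centre_ok[None]

    control_loss = _composite(neigh, eligible, neigh, window.compositing)
    with np.errstate(invalid="ignore"):
        delta_f = vals - control_loss
        is_pair = centre_ok & (eligible.sum(axis=0) >= 1) & (delta_f >= min_excess)
    delta_f = np.where(np.isfinite(delta_f), delta_f, np.nan)

    res = float(loss.attrs.get("resolution", np.nan))
    logger.info("find_pairs: %d deforested pixels of %d in-mask (window %dx%d, >=%.3g pp excess)",
                int(is_pair.sum()), int(mask_arr.sum()), window.size, window.size, min_excess)
    return PairSet(
        window=window,
        lat=loss["lat"].values,
        lon=loss["lon"].values,
        loss=vals,
        eligible=eligible,
        control_loss=control_loss,
        delta_f=delta_f,
        is_pair=is_pair,
        min_excess=min_excess,
        scale=res,
    )


def pair_delta_p(
    pairs: PairSet,
    cube: xr.DataArray,
    start_years,
    end_years,
    month_sel: np.ndarray | None = None,
) -> pd.DataFrame:
    """Compute ΔP and derived sensitivities for every pair.

    ΔP = (P_end − P_start) of the deforested pixel minus the same change
    composited over its eligible neighbours (neighbours whose period means
    are missing are dropped from the composite; the pair is dropped if none
    survive). Period means follow the multi-annual window convention, e.g.
    5-yr means 2003–2007 vs 2013–2017; ``month_sel`` restricts both periods
    to a per-pixel set of calendar months for the seasonal analysis.

    Returns one row per surviving pair with columns: ``row, col, lat, lon,
    scale, delta_f, n_ctl, control_loss, p_start_def, p_start_ctl, dp_def,
    dp_ctl, delta_p, rel_delta_p, sensitivity, rel_sensitivity``.
    """
    if cube.sizes["lat"] != pairs.lat.size or cube.sizes["lon"] != pairs.lon.size:
        raise ValueError("cube must be regridded to the pairing grid")

    p_start = period_mean(cube, start_years, month_sel).values
    p_end = period_mean(cube, end_years, month_sel).values
    change = p_end - p_start

    offsets = pairs.window.offsets
    neigh_change = _stack_neighbours(change, offsets)
    neigh_start = _stack_neighbours(p_start, offsets)
    neigh_loss = _stack_neighbours(pairs.loss, offsets)
    eligible = pairs.eligible & np.isfinite(neigh_change) & np.isfinite(neigh_start)

    rule = pairs.window.compositing
    dp_ctl = _composite(neigh_change, eligible, neigh_loss, rule)
    p_start_ctl = _composite(neigh_start, eligible, neigh_loss, rule)
    ctl_loss = _composite(neigh_loss, eligible, neigh_loss, rule)
    n_ctl = eligible.sum(axis=0)

    with np.errstate(invalid="ignore"):
        delta_f = pairs.loss - ctl_loss
        keep = (
            pairs.is_pair
            & (n_ctl >= 1)
            & np.isfinite(change)
            & np.isfinite(p_start)
            & (delta_f >= pairs.min_excess)
        )
    rows, cols = np.nonzero(keep)
    dp = change[keep] - dp_ctl[keep]
    df_excess = delta_f[keep]
    ps_def = p_start[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_dp = np.where(ps_def != 0, 100.0 * dp / ps_def, np.nan)

    out = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "lat": pairs.lat[rows],
            "lon": pairs.lon[cols],
            "scale": pairs.scale,
            "delta_f": df_excess,
            "n_ctl": n_ctl[keep],
            "control_loss": ctl_loss[keep],
            "p_start_def": ps_def,
            "p_start_ctl": p_start_ctl[keep],
            "dp_def": change[keep],
            "dp_ctl": dp_ctl[keep],
            "delta_p": dp,
            "rel_delta_p": rel_dp,
        }
    )
    out["sensitivity"] = out["delta_p"] / out["delta_f"]
    out["rel_sensitivity"] = out["rel_delta_p"] / out["delta_f"]
    if "category" in cube.attrs:
        out["category"] = cube.attrs["category"]
    logger.info("pair_delta_p: %d pairs with computable precipitation changes", len(out))
    return out


def climate_similarity_filter(
    pairs: pd.DataFrame, threshold: float = 0.10
) -> pd.DataFrame:
    """Retain pairs whose pre-deforestation climates are similar.

    Keeps pairs with ``|P_start,def − P_start,ctl| / P_start,def < threshold``
    (threshold as a fraction; the default 0.10 means "differed by less than
    10%"). Pairs with a zero start-period mean cannot be assessed and are
    dropped with a logged count.
    """
    zero = pairs["p_start_def"] == 0
    if zero.any():
        logger.warning("climate_similarity_filter: dropping %d pair(s) with zero start-period mean",
                       int(zero.sum()))
    ok = pairs.loc[~zero]
    rel = (ok["p_start_def"] - ok["p_start_ctl"]).abs() / ok["p_start_def"]
    kept = ok.loc[rel < threshold].reset_index(drop=True)
    logger.info("climate_similarity_filter: kept %d of %d pairs (threshold %.0f%%)",
                len(kept), len(pairs), 100 * threshold)
    return kept
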