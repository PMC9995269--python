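"""Sensitivity estimation: medians, significance tests, seasons, binned response.

The headline statistic is the median over pairs of per-pair sensitivity
ΔP/ΔF (mm/month per percentage point of forest loss), reported with the
standard error of the mean — median point estimate with mean-based error
bar — plus a seeded bootstrap SE of the median for internal use.
Significance compares the pooled deforested-pixel precipitation changes
against the pooled control changes with a two-sided Welch t-test and a
two-sided Mann–Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .pairing import PairSet, pair_delta_p

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityEstimate",
    "BinnedResponse",
    "estimate",
    "significance",
    "season_map",
    "season_selector",
    "seasonal_estimate",
    "binned_response",
    "elnino_stratify",
    "DEFAULT_BIN_EDGES",
]

SEASONS = ("dry", "transition", "wet")
#: forest-loss bin edges (pp) for the nonlinear response curve
DEFAULT_BIN_EDGES = (0.1, 5.0, 10.0, 20.0, 30.0, np.inf)


@dataclass
class SensitivityEstimate:
    """Median precipitation sensitivity to forest loss, with uncertainty.

    ``median`` is mm/month per pp; ``rel_median`` is % per pp; ``se`` is the
    standard error of the mean sensitivity (NaN when n < 2).
    """

    median: float
    rel_median: float
    se: float
    n: int
    p_t: float
    p_mw: float
    boot_se: float = np.nan
    scale: float = np.nan
    region: str | None = None
    category: str | None = None
    season: str = "annual"
    label: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def significance(pairs: pd.DataFrame) -> tuple[float, float]:
    """Two-sided Welch t and Mann–Whitney p-values: deforested vs control changes."""
    a = pairs["dp_def"].to_numpy(dtype=float)
    b = pairs["dp_ctl"].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        return np.nan, np.nan
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        logger.warning("significance: degenerate zero-variance groups; p-values undefined")
        return np.nan, np.nan
    p_t = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    p_mw = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return p_t, p_mw


def estimate(
    pairs: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    **labels,
) -> SensitivityEstimate:
    """Summarise pair records into the median-sensitivity estimate."""
    if len(pairs) == 0:
        raise ValueError("cannot estimate a sensitivity from an empty pair list")
    s = pairs["sensitivity"].to_numpy(dtype=float)
    rel = pairs["rel_sensitivity"].to_numpy(dtype=float)
    n = s.size
    med = float(np.median(s))
    rel_med = float(np.nanmedian(rel)) if np.isfinite(rel).any() else np.nan
    if n >= 2:
        se = float(np.std(s, ddof=1) / np.sqrt(n))
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_se = float(np.median(s[idx], axis=1).std(ddof=1))
    else:
        logger.warning("estimate: single pair; SE undefined and reported as missing")
        se = np.nan
        boot_se = np.nan
    p_t, p_mw = significance(pairs)
    scale = float(pairs["scale"].iloc[0]) if "scale" in pairs else np.nan
    category = labels.pop("category", pairs["category"].iloc[0] if "category" in pairs else None)
    return SensitivityEstimate(
        median=med, rel_median=rel_med, se=se, n=n, p_t=p_t, p_mw=p_mw,
        boot_se=boot_se, scale=scale, category=category, **labels,
    )


def season_map(cube: xr.DataArray) -> xr.DataArray:
    """Classify each pixel's calendar months into dry / transition / wet.

    The monthly climatology over the cube's full span ranks the 12 months
    per pixel: the 3 smallest are the dry season, the 3 largest the wet
    season, the remaining 6 the transition season. Ties are broken by
    ascending month index (stable sort). Pixels with a missing climatology
    month are left unclassified (all-NaN).

    Returns a DataArray with dims ``("month", "lat", "lon")`` and integer
    codes 0 = dry, 1 = transition, 2 = wet.
    """
    clim = cube.groupby("time.month").mean("time", skipna=False)
    clim = clim.transpose("month", "lat", "lon")
    vals = clim.values
    order = np.argsort(vals, axis=0, kind="stable")
    codes = np.ones_like(vals, dtype=float)  # transition by default
    np.put_along_axis(codes, order[:3], 0.0, axis=0)
    np.put_along_axis(codes, order[-3:], 2.0, axis=0)
    codes[:, ~np.isfinite(vals).all(axis=0)] = np.nan
    return xr.DataArray(
        codes,
        dims=("month", "lat", "lon"),
        coords={"month": np.arange(1, 13), "lat": cube["lat"], "lon": cube["lon"]},
        name="season_code",
        attrs={"codes": "0=dry 1=transition 2=wet"},
    )


def season_selector(smap: xr.DataArray, season: str) -> np.ndarray:
    """Boolean (12, nlat, nlon) month selector for one season."""
    code = {"dry": 0, "transition": 1, "wet": 2}[season]
    return smap.values == code


def seasonal_estimate(
    pairs: PairSet,
    cube: xr.DataArray,
    smap: xr.DataArray,
    start_years,
    end_years,
    seasons=SEASONS,
    filter_threshold: float | None = None,
    **estimate_kw,
) -> dict[str, SensitivityEstimate]:
    """Per-season sensitivity estimates (period means restricted to season months)."""
    from .pairing import climate_similarity_filter

    out: dict[str, SensitivityEstimate] = {}
    for season in seasons:
        sel = season_selector(smap, season)
        df = pair_delta_p(pairs, cube, start_years, end_years, month_sel=sel)
        if filter_threshold is not None:
            df = climate_similarity_filter(df, filter_threshold)
        out[season] = estimate(df, season=season, **estimate_kw)
    return out


@dataclass
class BinnedResponse:
    """Piecewise-constant sensitivity as a function of forest-loss magnitude."""

    edges: np.ndarray                    # (nbin + 1,) strictly increasing, pp
    median: np.ndarray                   # (nbin,) mm/month per pp, NaN where empty
    n: np.ndarray                        # (nbin,) pairs per bin
    se: np.ndarray = field(default=None)

    def sensitivity_at(self, loss: np.ndarray) -> np.ndarray:
        """Bin sensitivity for each loss value; losses above the top edge use
        the top bin, losses below the lowest edge yield NaN."""
        loss = np.asarray(loss, dtype=float)
        idx = np.digitize(loss, self.edges[1:-1], right=False)
        idx = np.clip(idx, 0, len(self.median) - 1)
        out = self.median[idx]
        out = np.where(loss < self.edges[0], np.nan, out)
        return np.where(np.isfinite(loss), out, np.nan)


def binned_response(pairs: pd.DataFrame, edges=DEFAULT_BIN_EDGES) -> BinnedResponse:
    """Median sensitivity within each forest-loss bin (left-closed, right-open)."""
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    loss = pairs["delta_f"].to_numpy(dtype=float)
    s = pairs["sensitivity"].to_numpy(dtype=float)
    nbin = edges.size - 1
    med = np.full(nbin, np.nan)
    se = np.full(nbin, np.nan)
    counts = np.zeros(nbin, dtype=int)
    idx = np.digitize(loss, edges, right=False) - 1
    for b in range(nbin):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b] > 0:
            med[b] = float(np.median(s[sel]))
        if counts[b] > 1:
            se[b] = float(np.std(s[sel], ddof=1) / np.sqrt(counts[b]))
        if 0 < counts[b] < 10:
            logger.warning("binned_response: bin [%.3g, %.3g) has only %d pair(s)",
                           edges[b], edges[b + 1], counts[b])
    if counts.sum() == 0:
        raise ValueError("no pairs fall in any forest-loss bin")
    return BinnedResponse(edges=edges, median=med, n=counts, se=se)


def elnino_stratify(
    cover: xr.DataArray,
    mask: xr.DataArray,
    cube: xr.DataArray,
    windows: dict[str, tuple],
    window=None,
    min_excess: float | None = None,
    **estimate_kw,
) -> dict[str, SensitivityEstimate]:
    """One sensitivity estimate per analysis-window configuration.

    ``windows`` maps a label (e.g. ``"3yr_incl_nino"``) to a
    ``(start_years, end_years)`` tuple. The whole pipeline — loss
    differencing over the windows, pairing, ΔP — is re-run per
    configuration, so that comparing windows that include or exclude El
    Niño years isolates any interaction between ENSO state and the
    forest-loss response (a purely additive basin-wide anomaly cancels in
    the pairing and leaves the estimates window-invariant). Estimates are
    never pooled across configurations.
    """
    from .grids import cover_loss
    from .pairing import MIN_EXCESS_PP, WindowSpec, find_pairs

    if len(windows) < 2:
        raise ValueError("need at least two window configurations to stratify")
    window = window or WindowSpec()
    min_excess = MIN_EXCESS_PP if min_excess is None else min_excess
    out: dict[str, SensitivityEstimate] = {}
    for label, (start_years, end_years) in windows.items():
        loss = cover_loss(cover, start_years, end_years)
        pairs = find_pairs(loss, mask, window, min_excess)
        df = pair_delta_p(pairs, cube, start_years, end_years)
        out[label] = estimate(df, label=label, **estimate_kw)
    return out


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Tabulate SensitivityEstimate objects (list or dict) as a DataFrame."""
    if isinstance(estimates, dict):
        estimates = list(estimates.values())
    elif isinstance(estimates, SensitivityEstimate):
        estimates = [estimates]
    return pd.DataFrame([e.to_dict() for e in estimates])
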