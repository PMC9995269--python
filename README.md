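# rainfor

Observational attribution of tropical precipitation change to forest loss.

Deforestation suppresses evapotranspiration and moisture recycling, and so
can reduce rainfall over and around cleared tropical forest. Detecting that
signal in observations is hard: precipitation is noisy, trends are shared
across whole basins (ENSO, decadal variability, dataset biases), and forest
loss is spatially patchy. `rainfor` implements the standard observational
answer to this problem — a **moving-window nearest-neighbour estimator** —
as a tested, reusable pipeline for researchers in land–atmosphere
interactions and ecohydrology, together with a synthetic-data generator
with a *known injected sensitivity* so that the entire pipeline can be
verified by parameter recovery, without downloading any multi-GB forest or
precipitation product.

## The estimator

For each pixel of a forest-loss grid (inside an evergreen-broadleaf biome
mask, at each analysis scale), the pixel's *control* is the composite of
its 3×3 (or 5×5) window neighbours with strictly less forest loss. A pixel
is a *deforested pixel* when its loss exceeds the control's by at least

    ΔF = F_deforested − F_control ≥ 0.1 pp.

With multi-annual mean precipitation at the start and end of the record
(e.g. 2003–2007 vs 2013–2017), each pair contributes

    ΔP = (P_end − P_start)_deforested − (P_end − P_start)_control,

which cancels *any* signal shared across the window — basin-wide trends,
El Niño anomalies, dataset offsets — leaving the local response to the
local loss contrast. The headline statistic is the **median of ΔP/ΔF over
pairs** (mm month⁻¹ per percentage point of forest loss; the relative
version (ΔP/P)/ΔF is in % per pp), reported with the standard error of the
mean, a two-sided Welch *t*-test and a Mann–Whitney *U* test of deforested
vs control changes. Downstream stages provide per-pixel wet/dry/transition
season decomposition, a binned (loss-magnitude-dependent) response curve,
window-stratified estimates (El Niño vs non-El Niño periods), and
projection of future precipitation change from forest-loss scenarios in
linear, 30-pp-capped and binned-nonlinear modes with ±1 SE bands.

## Worked example

Recover an injected drying response of −0.25 mm month⁻¹ pp⁻¹ from a
synthetic world (64×64 grid, 15 years of monthly precipitation, interannual
noise σ = 10 mm/month):

```python
import rainfor as rf
from rainfor.grids import cover_loss

config = rf.SynthConfig(shape=(64, 64), beta=-0.25, sigma=10.0, seed=1)
bundle = rf.generate_bundle(config)

start, end = range(2003, 2008), range(2013, 2018)
loss = cover_loss(bundle.cover, start, end)
pairs = rf.find_pairs(loss, bundle.mask, rf.WindowSpec(size=3))
records = rf.pair_delta_p(pairs, bundle.precip, start, end)
est = rf.estimate(records)
```

This prints (via the obvious `print` statements):

```
pairs: 1287
median sensitivity: -0.239 +/- 0.167 mm/month per pp (true -0.250)
relative sensitivity: -0.239 % per pp
Welch t p-value: 1.65e-49   Mann-Whitney p-value: 1.34e-38
```

The estimator recovers the injected β within its sampling spread, and both
tests reject the null of equal deforested/control changes. Projecting the
bundle's future loss scenario with the recovered sensitivity, capped at the
observationally well-sampled 30 pp:

```python
proj = rf.project_capped(bundle.future_loss, est, cap=30.0)
summary = rf.regional_summary(
    proj, {"domain": bundle.future_loss >= 0},
    baseline=bundle.precip.mean("time"),
)
```

```
region     dp  dp_lower  dp_upper  rel_dp_pct
domain -1.383     -2.35    -0.416      -1.387
```

i.e. a domain-mean drying of 1.4 mm month⁻¹ (−1.4 % of baseline rainfall)
by the end of the scenario, with the ±1 SE range from the sensitivity's
uncertainty.

A command-line interface mirrors the library:
`rainfor simulate | aggregate | pairs | estimate | seasons | project | run`
(see `rainfor --help`); `rainfor run --config pipeline.yaml` drives the
whole chain (aggregate → regrid → pair → estimate → seasonal → project)
and writes pair CSVs, estimate tables, projection NetCDFs and a manifest.

## Layout

- `rainfor.synthetic` — the synthetic world: clustered forest-loss
  histories, biome masks, monthly precipitation with seasonal cycle, noise,
  optional El Niño anomalies and a linear or saturating injected response.
- `rainfor.grids` — multi-scale aggregation (area-weighted, conserving
  lost forest area), bilinear/conservative regridding, multi-annual period
  means, window-consistent loss differencing.
- `rainfor.pairing` — the moving-window nearest-neighbour pairing, ΔP
  computation and the pre-deforestation climate-similarity filter.
- `rainfor.sensitivity` — median sensitivities with SEs and significance
  tests, per-pixel season classification, seasonal and binned estimates,
  window stratification.
- `rainfor.projection` — linear / capped / binned-nonlinear projection and
  cos-latitude regional summaries.
- `rainfor.io`, `rainfor.cli` — NetCDF/CSV/JSON/YAML I/O, the pipeline
  driver and the CLI.

See `docs/methods.md` for the model assumptions, parameter choices,
numerical conventions and known limitations.
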