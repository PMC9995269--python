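# Methods

This note documents the estimator, the synthetic world used to verify it,
the parameter and numerical choices that matter, and what the tests do and
do not demonstrate about real data.

## 1. The moving-window nearest-neighbour estimator

**Pairing.** On a regular lat/lon grid of forest-cover loss (percentage
points over the analysis period), every in-mask, non-missing pixel is
compared with its window neighbours (3×3 default, 5×5 supported; windows
truncate at domain edges so border pixels are retained). Neighbours are
*eligible* for the control when they are in-mask, non-missing and have
**strictly** less loss than the centre — a tie carries no treatment
contrast. The control is the unweighted mean over eligible neighbours
(lowest-variance local counterfactual); a single minimum-loss-neighbour
variant is available (`WindowSpec(compositing="min")`). A pixel becomes a
deforested pixel when ΔF = centre loss − control loss ≥ 0.1 pp. Every
pixel is evaluated independently, so a deforested pixel can also serve
inside another pixel's control; pair counts are monotonically
non-increasing in the excess threshold, and 5×5 eligible sets are
supersets of the 3×3 sets.

**Differencing.** Precipitation change is the difference of multi-annual
window means (default 5-yr: 2003–2007 vs 2013–2017; 3-yr variants are
config). ΔP subtracts the control's change from the deforested pixel's,
which removes *exactly* any pixel-independent signal (trends, additive
ENSO anomalies, dataset offsets) — a property the tests assert to 1e-9.
The per-pair sensitivity is ΔP/ΔF (mm month⁻¹ pp⁻¹) and the relative
version divides ΔP by the deforested pixel's start-period mean
(% per pp).

**Window-consistent loss.** The loss denominator is differenced over the
*same* start/end windows as precipitation
(`grids.cover_loss(cover, start_years, end_years)`). If instead the
total-period loss were paired with window-mean precipitation changes, the
recovered slope would be attenuated by the ratio of the loss realised
between window midpoints to the total loss (50/70 for the defaults) —
with consistent windows the noiseless recovery of an injected linear
sensitivity is exact, which the test suite asserts to 1e-9.

**Statistics.** The point estimate is the median over pairs; the error bar
is the standard error of the *mean* sensitivity (this deliberate
median-point/mean-SE pairing is the field's reporting convention for this
analysis, and a seeded 1,000-resample bootstrap SE of the median is also
stored). Significance compares the pooled deforested changes against the
pooled control changes with a two-sided Welch *t*-test and a two-sided
Mann–Whitney *U*; degenerate zero-variance inputs yield missing p-values
with a warning. No multiple-testing correction is applied (per-panel tests
only) — a known limitation. Note that the pooled tests inherit spatial
dependence from overlapping windows: neighbouring pairs share pixels, so
under a true null the tests are *conservative* (≈1 % rejection at α=0.05
in synthetic replicates). The null-calibration test therefore thins pairs
to spatially disjoint windows (stride 3), which restores independence and
the nominal ≈5 % rate; users testing hypotheses on dense pair sets should
expect conservative p-values rather than inflated ones.

**Climate-similarity filter.** Optionally, pairs whose pre-deforestation
(start-window) means differ by ≥10 % of the deforested pixel's mean are
discarded; pairs with a zero start mean cannot be assessed and are dropped
with a logged count.

**Seasons.** Each pixel's 12 calendar months are ranked by the monthly
climatology over the full record of the same dataset: the 3 smallest are
the dry season, the 3 largest the wet season, the remaining 6 the
transition season (contiguity not required; ties broken deterministically
by ascending month index via a stable sort). Seasonal sensitivities rerun
the identical pipeline with period means restricted to each pixel's season
months. An effect confined to the 3 driest months therefore appears at 4×
strength in the dry-season estimate and vanishes from the wet season —
asserted exactly in the noiseless tests.

**Binned response.** Pairs are assigned to forest-loss bins by ΔF
(left-closed, right-open; default edges 0.1, 5, 10, 20, 30, ∞ pp — the
edges are config since no canonical set exists) and each bin reports its
median sensitivity and n; empty bins are missing, never zero, and thin
bins are flagged.

**Window stratification.** `elnino_stratify` re-runs the *whole* chain
(loss differencing, pairing, ΔP) per labelled (start, end) configuration
and never pools across configurations. Because additive anomalies cancel
in the pairing, window choice changes nothing unless the response itself
differs between periods — e.g. a multiplicative El Niño interaction —
which is exactly what comparing El Niño-containing and El Niño-free
windows isolates.

## 2. Grid operations

* **Aggregation** (only coarsening): a coarse cell is the area-weighted
  mean of its factor×factor block, with weights the exact spherical band
  areas Δλ·(sin(φ+Δφ/2) − sin(φ−Δφ/2)). With exact band areas the total
  lost forest area Σ(loss × area) is conserved to machine precision
  (asserted at 1e-9 relative). Missing fine cells are excluded from the
  weights; a coarse cell is missing when >50 % of its block area is
  missing; edge-partial blocks are dropped with a logged warning.
* **Regridding**: bilinear interpolation of cell-centre values (months
  independent; exact for planar fields, asserted at 1e-10); an exact
  area-weighted block mean is available as the "conservative" option for
  aligned integer coarsenings. Cross-checked in tests against an
  independent `RegularGridInterpolator` implementation.
* **Period means**: mean over all months of the listed years; a pixel is
  missing if *any* contributing month is missing (avoids seasonally biased
  means). Linearity of the mean is property-tested.
* Coordinates are cell-centre degrees on regular grids; geographic lat/lon
  only, no antimeridian crossing.

## 3. The synthetic world

The generator is a test fixture, not a climate model: it produces the four
pipeline inputs with a known ground truth.

* **Cover**: baseline ≈90 % (±3 % spatial noise, clipped to [0, 100])
  minus clustered loss. Loss patches are Gaussian bumps combined by
  pointwise maximum — sharp at the pixel scale (decay 0.6 px) with
  magnitudes uniform in [0.1, 1]×max_loss (default max 50 pp; the first
  patch attains the maximum exactly). Sharp, varied patches matter for
  identifiability: the controls of patch pixels then carry near-zero loss,
  so the pair-level contrast ΔF tracks the absolute loss magnitude and
  spans the binned-response range (~0–45 pp), as fine-resolution
  forest-change data do. Each patch is cleared as a linear ramp over a
  configurable period, by default 2008–2012 — the interior of the record —
  so the full contrast and its precipitation response are expressed
  between the default early/late analysis windows (a whole-record ramp,
  `loss_period=None`, leaves the response partially realised in the end
  window and attenuates nonlinear bin estimates). Cover is loss-only
  (monotonically non-increasing) and capped at the pixel's baseline.
* **Precipitation**: per pixel and month,
  `P = clim + noise + enso + response`, floored at 0. `clim` is a
  sinusoidal seasonal cycle (mean 100 mm/month, amplitude 40, random
  per-pixel phase). `noise` is iid Gaussian per pixel-*month* by default
  (σ = 10 mm/month); a per pixel-*year* variant (same draw added to all 12
  months) is available but makes multi-annual window means ~3.5× noisier
  and is not the default. `enso` is an additive, spatially uniform anomaly
  in configured El Niño years; optionally those years also multiply the
  response (the recoverable "stronger response in El Niño years" truth).
  `response` is β×L (linear) or β·H·L/(H+L) (saturating; initial slope β,
  half-saturation H = 30 pp by default, echoing the 30 pp well-sampled
  threshold), applied to the cumulative realised loss each year. Noise
  draws are independent of β, so a β = 0 rerun with the same seed is an
  exact counterfactual — several tests rely on this.
* **Scenario**: per-pixel future loss in [0, 100] pp, either uniform or
  clustered with broader patches (decay 2.5 px, heights spanning both
  sides of the 30 pp cap).
* **Determinism**: one seed drives three independent child streams
  (cover, precipitation, scenario); identical config + seed reproduces the
  bundle bitwise.

**What passing tests show — and don't.** Parameter recovery on this world
verifies the estimator's logic: differencing, window consistency, seasonal
decomposition, bin assignment, projection modes. It does *not* validate
the causal interpretation on real data, where loss is not randomly placed,
precipitation noise is spatially correlated and non-Gaussian, ENSO
teleconnections have spatial structure, and land-cover and rainfall
datasets carry their own biases. The generator's iid noise in particular
makes the significance tests better behaved than they would be on real
fields.

## 4. Projection

* **Linear**: ΔP = loss × median sensitivity; bounds at median ± 1 SE
  (pixelwise lower ≤ central ≤ upper, since loss ≥ 0).
* **Capped**: loss truncated at 30 pp (config), the observationally
  well-sampled range; equals linear exactly wherever loss ≤ cap and is
  strictly smaller in magnitude above it.
* **Nonlinear**: piecewise-constant binned sensitivity applied to the
  *total* projected loss (losses above the top bin use the top bin; below
  the lowest edge the change is zero; pixels falling in an empty bin are
  missing). The alternative piecewise-*integral* reading (accumulate each
  traversed bin's sensitivity over its loss increment) is available via
  `piecewise="integral"`; the piecewise-constant form is the default.
* **Scenario preprocessing**: multi-category cover is summed over
  categories and differenced against a 2015 baseline year, gains clipped
  to zero (`projection.scenario_loss`).
* **Regional summaries**: cos-latitude area-weighted means of ΔP and of
  the bounds; relative change is the ratio of the regional mean ΔP to the
  regional mean baseline precipitation, in percent.
* One tropical sensitivity is applied across regions by default (the
  observational analysis transfers the tropical satellite response);
  per-region sensitivities are a config option in the pipeline driver.
* The crop-yield chain multiplies the relative sensitivity (% per pp) by
  the loss (pp) and a yield elasticity to precipitation (default 0.5 % per
  %): 0.25 %/pp × 10 pp × 0.5 = 1.25 % yield decline.

## 5. Numerical and design conventions

* Problem sizes in the test and acceptance runs — 64×64 pixels × 180
  months, 20-seed replicate loops, 500 null replicates — are chosen so the
  full suite runs in well under a minute of compute per criterion while
  leaving each check statistically well-powered.
* Season ties: ascending month index (stable sort), documented above.
* Aggregation missing rule (>50 % of block area) and the any-month-missing
  period-mean rule are deliberate conservative defaults and configurable.
* NetCDF I/O uses the NetCDF3-classic backend for maximal portability;
  precipitation units are normalised on read (mm/day converted with each
  month's day count; unrecognised units are a hard error). Only
  standard-calendar monthly time axes are accepted; 360-day calendars are
  out of scope for the reader.
* Masks are NetCDF; GeoTIFF ingestion is out of scope in this build.
* The pipeline driver writes a manifest (config hash, per-stage counts,
  validity flag); any stage failure aborts with a stage-labelled error and
  marks the manifest invalid.

## 6. Known limitations

* No spatial-autocorrelation correction in the significance tests (the
  pooled tests are conservative under dependence, see §1) and no
  multiple-testing correction across panels.
* The nearest-neighbour design estimates the *local* (within-window)
  response only; nonlocal moisture-recycling effects, downwind
  redistribution and directional (upwind/downwind) pairing are out of
  scope.
* Binned sensitivities index pairs by the local contrast ΔF; they
  approximate the response at an absolute loss level only when controls
  carry little loss (sharp loss frontiers), which holds in the synthetic
  default and in fine-resolution loss data but may not at very coarse
  scales.
* The projection assumes the historical sensitivity transfers to future
  loss; feedbacks, tipping behaviour and climate-model coupling are out of
  scope.
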