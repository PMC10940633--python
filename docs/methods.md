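# Methods

This note documents the models, conventions and numerical choices behind
`refugia-sdm`, and what the synthetic seascape does and does not emulate.

## Spatial conventions

All rasters live on a regular geographic (lon/lat) grid with **cell-center
registration**: `GridSpec.lon_min`/`lat_min` are the centers of the
south-west cell, row 0 is the northernmost row. Nodata is an explicit
boolean mask; every operation that consumes a nodata cell emits nodata
rather than imputing (resampling, slope, prediction, classification). Cell
areas use the spherical element `A = R²·Δλ·(sin φ_top − sin φ_bottom)` with
R = 6371 km, so area accounting is exact on the sphere and all area
identities in the change and overlay tables hold to machine precision.

GeoTIFF I/O is single-band float32 with the grid encoded in the standard
pixel-scale/tiepoint tags and nodata in the `GDAL_NODATA` tag; projected
CRSs and multi-band files are rejected rather than guessed at.

Horn's eight-neighbor slope uses per-row metric conversion
(`dx = Δ°·(π/180)·R·cos φ`, `dy = Δ°·(π/180)·R`). On a degree grid there is
no single "cell size in meters"; scaling dx by the row's cosine is the
standard treatment and reproduces analytic plane gradients exactly (tested).

## Data preparation

Pseudo-absences are implanted only inside declared presence-only zones, at
the **global** survey presence/absence ratio (the ratio is not defined
regionally for a survey that does not cover those zones), at uniformly
random unoccupied cell centers no deeper than 1000 m. If a zone has fewer
eligible cells than the ratio asks for, the shortfall is logged and the zone
is left partially filled rather than violating the depth or occupancy
constraints.

Aggregation keeps one record per cell with presence priority: a single
detection is taken as evidence the cell's conditions are suitable, and
"noisy absences" sharing a presence cell are discarded. Aggregation is
idempotent and never loses an occupied presence cell (both property-tested).

## Cross-validation design

Blocks are square checkerboard tiles of 250 km, converted to degrees with
1° latitude = 111.19 km and the longitude scale taken at the dataset's mean
latitude. Occupied blocks are shuffled (seeded) and dealt **round-robin**
into 5 folds: block counts per fold differ by at most one and no fold can be
empty, which a fully random block→fold draw does not guarantee. Each of the
30 repeats redraws the assignment. Records of one block never straddle
train/test.

A held-out fold that contains a single class cannot be evaluated; such runs
are recorded as failed and excluded before retention. Under the default
synthetic conditions all 300 runs succeed.

## Learners

* **GAM** — binomial likelihood, logit link, one cubic B-spline smooth per
  predictor with basis dimension 4 (three free columns per smooth after the
  identifiability constraint, plus a shared intercept), fitted unpenalized
  by IRLS. Prediction clamps each predictor to its training range before
  evaluating the spline basis — plateau extrapolation, which keeps
  probability maps stable in cells outside the sampled environmental range.
* **Random forest** — 500 CART trees by default (100–150 in the fast test
  profiles), `sqrt(p)` candidate predictors per split, unlimited depth,
  probabilities as class-vote fractions, deterministic given its seed.

Both expose `predict(table) → probability`, so the CV engine, the
importance and response-curve code run unchanged with either.

Response curves use the **partial-dependence** convention: x sweeps the
background's observed range; y(x) is the mean prediction over background
rows with that one predictor overwritten. Each row's curve peaks where the
generating depth term peaks, so the convention is unbiased for additive
truths; it is well defined for both learners, which is why it was chosen
over holding covariates at their means. Backgrounds larger than 250 rows
are subsampled (seeded) for tractability.

Permutation importance is the mean held-out AUC loss over (default) 10
permutations of one predictor column at a time; negative losses are
reported as-is.

## Thresholds and the ensemble

Classification is **closed on the presence side** (`score ≥ t` ⇒ presence)
everywhere. The TSS-optimal threshold scans the sorted unique scores plus
{0, 1} and returns the **smallest** maximizer — ties favor sensitivity,
appropriate for an indicator species where missing true habitat is the
costlier error.

Retention removes the `⌊n/4⌋` lowest-AUC runs (ties broken by run id), a
count-based reading of "discard the first quartile" that maps 300 → 225
regardless of AUC ties; a strict value rule (`AUC < Q1`) can drop fewer
under ties. The ensemble surface is the plain mean of the retained binary
maps — suitability values are multiples of 1/n_retained — and the future
map uses each run's *own* (present-derived) threshold, so present/future
differences reflect the predictors, not threshold drift.

## Uncertainty surfaces

* Calibration: per-cell mean/population-sd of the retained binary maps, an
  inverse coefficient of variation (high = agreement). Cells where all
  models agree have sd 0 and are emitted as nodata with a count, rather
  than an infinity.
* Algorithm disagreement: the full ensemble methodology (mean of binaries +
  own TSS threshold) applied separately to retained GAMs and RFs, then
  cross-tabulated into both/gam-only/rf-only classes.
* Kriged occurrence: ordinary kriging of survey 0/1 detections (pseudo-
  absences excluded by contract) with a variogram fitted by pair-count-
  weighted least squares (spherical by default, exponential available).
  The system is solved once by LU factorization and back-substituted for
  all cells; weights sum to 1 by construction (asserted in tests).
  Duplicate stations are averaged before assembly; a 1e-10 diagonal jitter
  keeps the zero-nugget system well-posed while preserving exact
  interpolation to ~1e-8. The 20-km "buffer" is a prediction mask — no
  prediction farther than 20 km from a station — not a search
  neighborhood, and the kriged surface is binarized at 0.5 for the
  model-vs-observation agreement classes.

## Projection, refugia and risk

The future stack replaces temperature, salinity and current velocity;
terrain is fixed. Cells deeper than 2000 m are masked before change
classification (the study domain). The headline loss statistic is
`area(loss)/(area(loss)+area(refugia))·100` — the share of *presently
suitable* area lost — reported both area-weighted (primary) and
cell-counted.

Fishing-effort risk classes are quartiles of the **positive**-effort cells
(linear-interpolation quantiles); zero-effort cells form their own class,
mirroring effort products whose lowest reported bin starts above zero.
Classes are rank-based and invariant to monotone rescaling of the effort
field. Edges are always recomputed from the data, never hard-coded.

## The synthetic seascape

The generator emulates an enclosed sea: a central deep basin (~2500 m)
ringed by continental shelf and slope, so mid-depth habitat occurs in every
quadrant and spatial blocks everywhere contain both classes. Smooth fields
are Gaussian-filtered white noise (kernel 4 cells; 8 cells for the
temperature gradient), giving the spatial autocorrelation that makes block
CV meaningfully different from random CV.

True suitability (logit scale): intercept −4, plus Gaussian bumps in depth
(optimum 650 m, sd 250 m, amplitude 4 — the dominant term), salinity
(38.8 ± 0.25 psu, amplitude 1) and current speed (0.01 ± 0.012 m/s,
amplitude 1), plus 0.05·slope°, minus 1.0 logit per °C of bottom
temperature above 13.75 °C. Temperature is 13 °C + 5.5 °C·exp(−depth/400 m)
plus an independent lateral gradient of sd 1.0 °C (the scale of the real
east–west Mediterranean difference at equal depth); without that
independent variation temperature is a deterministic function of depth and
the two GAM smooths cannot be separated. The future scenario adds the
warming parameter (default 1.5 °C, within the projected 1–2 °C bottom
anomaly) plus small salinity/current perturbations. Fishing effort is a
patchy log-normal field confined to the 200–800 m trawling band; regions
are three longitude bands.

Survey stations fall uniformly on cells shallower than 2000 m outside the
presence-only boxes with Bernoulli(truth) detection; presence-only records
are drawn proportionally to truth inside their boxes (restricted to the
<2000 m study domain, since deep presence-only records would have no
absence counterweight).

What the generator does **not** emulate: real coastline geometry,
interannual dynamics, detectability differences between gears, historical
trawling-induced absences, and spatially varying survey effort. Passing
tests therefore demonstrate that the pipeline recovers known responses
from spatially structured presence/absence data of realistic size and
prevalence (~15–25 %) — not that any particular real-world map is correct.

## Problem sizes and profiles

The default configuration is the full study design (250-km blocks, 5 folds,
30 repeats, both algorithms, k = 4, 500 trees, quartile retention, 20-km
kriging buffer). Test and example profiles keep the design but shrink
per-model cost (60×60 grid with ~550–900 aggregated records and 40–100
trees for the 300-run bookkeeping; a 100×100 grid with ~3600 records, 5
repeats and 150 trees for parameter recovery), chosen so the whole suite
runs in a couple of minutes while every structural property of the full
design is still exercised. The acceptance script reports which experiment
each number comes from via its `n` field.

## Known limitations

* The GAM's plateau extrapolation differs from mgcv's linear extrapolation
  outside the training range; maps in strongly extrapolated cells are
  conservative.
* With k = 4 the depth smooth is a broad hump; its argmax is estimated to
  roughly ±100 m under collinearity with temperature, which is why the
  recovery check uses a band (550–750 m) around the generating optimum
  rather than a point.
* Unpenalized fitting means the GAM can be overconfident at small fold
  sizes; the quartile retention step exists precisely to drop such runs.
* Ordinary kriging is run globally (all stations in one system), which is
  exact but O(n²) memory in stations; beyond ~10⁴ stations a neighborhood
  search would be needed.
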