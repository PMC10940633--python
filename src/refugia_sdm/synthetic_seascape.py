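"""Synthetic deep-sea seascape generator.

Builds a present-day and a warmed-future predictor stack (bathymetry, slope,
bottom temperature, bottom salinity, current velocity), a known "true"
suitability surface for a bathyal soft-bottom coral, survey and presence-only
occurrence records, a patchy trawling-effort field and region labels.  The
truth surface has a depth optimum near 650 m, a salinity optimum near
38.8 psu, a low-current optimum and suitability that declines once bottom
temperature exceeds a threshold — so a fitted model can be checked against a
known response in every predictor.

Spatial structure comes from Gaussian-filtered white noise, which gives the
smooth autocorrelated fields that make spatial block cross-validation matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .raster_core import GridSpec, PredictorStack, RasterLayer, RasterError, horn_slope

PREDICTOR_NAMES = ("bathymetry", "slope", "temperature", "salinity", "current_velocity")
#: Predictors replaced in the future scenario (the terrain ones are fixed).
CLIMATE_PREDICTORS = ("temperature", "salinity", "current_velocity")


@dataclass
class TruthParams:
    """Parameters of the generating suitability model (logit scale).

    The truth is ``logistic(intercept + Gaussian bumps in depth, salinity and
    current + a hinge decline above temp_max + slope_effect * slope)``.
    """

    depth_opt: float = 650.0        # m below sea level (positive depth)
    depth_sd: float = 250.0         # m
    depth_amp: float = 4.0          # logit units at the optimum
    temp_max: float = 13.75         # degC; suitability declines above this
    temp_decline: float = 1.0       # logit units lost per degC above temp_max
    sal_opt: float = 38.8           # psu
    sal_sd: float = 0.25            # psu
    sal_amp: float = 1.0
    curr_opt: float = 0.01          # m/s
    curr_sd: float = 0.012          # m/s
    curr_amp: float = 1.0
    slope_effect: float = 0.05      # logit units per degree of slope
    intercept: float = -4.0
    warming: float = 1.5            # degC added to the future temperature field

    def __post_init__(self) -> None:
        if min(self.depth_sd, self.sal_sd, self.curr_sd) <= 0:
            raise ValueError("spread parameters must be > 0")
        if self.warming < 0:
            raise ValueError("warming must be >= 0")


@dataclass
class SurveyDesign:
    """Sampling design for synthetic occurrence records.

    Survey stations fall uniformly on cells shallower than ``max_survey_depth``
    outside the presence-only boxes; detection is Bernoulli(truth).  Records
    in the presence-only boxes are sampled proportionally to truth and are all
    detections, emulating ROV/literature presence-only sources.
    """

    n_survey_stations: int = 800
    presence_only_regions: list[tuple[float, float, float, float]] = field(
        default_factory=list)  # (lon_min, lat_min, lon_max, lat_max)
    n_presence_only: int = 0
    max_survey_depth: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_survey_stations < 0 or self.n_presence_only < 0:
            raise ValueError("counts must be >= 0")


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field (filtered white noise)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def truth_logit(params: TruthParams, depth_m: np.ndarray, slope_deg: np.ndarray,
                temp_c: np.ndarray, sal_psu: np.ndarray,
                curr_ms: np.ndarray) -> np.ndarray:
    """Generating model on the logit scale; ``depth_m`` positive below sea level."""
    z = np.full(np.shape(depth_m), params.intercept, dtype=float)
    z += params.depth_amp * np.exp(-0.5 * ((depth_m - params.depth_opt) / params.depth_sd) ** 2)
    z += params.sal_amp * np.exp(-0.5 * ((sal_psu - params.sal_opt) / params.sal_sd) ** 2)
    z += params.curr_amp * np.exp(-0.5 * ((curr_ms - params.curr_opt) / params.curr_sd) ** 2)
    z -= params.temp_decline * np.clip(temp_c - params.temp_max, 0.0, None)
    z += params.slope_effect * slope_deg
    return z


def generate_seascape(grid: GridSpec, params: TruthParams | None = None,
                      seed: int = 0, smoothness_cells: float = 4.0) -> dict:
    """Generate co-registered layers for one synthetic study area.

    Returns a dict with keys ``present``/``future`` (:class:`PredictorStack`),
    ``truth``/``truth_future`` (suitability in [0, 1] on the respective
    stacks), ``fishing`` (h km⁻² yr⁻¹) and ``regions`` (integer labels).
    """
    if params is None:
        params = TruthParams()
    if grid.n_rows < 50 or grid.n_cols < 50:
        raise RasterError("seascape grid must be at least 50x50 for spatial structure")
    rng = np.random.default_rng(seed)
    shape = grid.shape

    # bathymetry: central deep basin ringed by continental shelf and slope
    # (margins on every side, like an enclosed sea), plus smooth relief
    xfrac = np.linspace(0.0, 1.0, grid.n_cols)[None, :] * np.ones((grid.n_rows, 1))
    yfrac = np.linspace(0.0, 1.0, grid.n_rows)[:, None] * np.ones((1, grid.n_cols))
    r = np.hypot(xfrac - 0.5, yfrac - 0.5)
    relief = _smooth_field(rng, shape, smoothness_cells)
    depth = 2500.0 / (1.0 + np.exp(-9.0 * (0.40 - r))) + 180.0 * relief
    depth = np.clip(depth, 2.0, None)        # positive depth, m
    bathy = RasterLayer(grid, -depth, np.zeros(shape, bool),
                        name="bathymetry", units="m")

    slope = horn_slope(bathy)
    # the slope border is nodata by construction; keep it, downstream drops it

    # temperature decreases with depth towards a ~13 degC deep layer, plus a
    # basin-scale lateral gradient independent of depth (~1 degC sd, as
    # between the warm eastern and cool western Mediterranean sub-basins);
    # the lateral term keeps temperature separable from bathymetry in a fit
    lateral = _smooth_field(rng, shape, smoothness_cells * 2)
    temp = 13.0 + 5.5 * np.exp(-depth / 400.0) + 1.0 * lateral
    temperature = RasterLayer(grid, temp, np.zeros(shape, bool),
                              name="temperature", units="degC")

    sal = 38.8 + 0.3 * _smooth_field(rng, shape, smoothness_cells)
    salinity = RasterLayer(grid, sal, np.zeros(shape, bool),
                           name="salinity", units="psu")

    curr = np.exp(np.log(0.012) + 0.8 * _smooth_field(rng, shape, smoothness_cells))
    current = RasterLayer(grid, curr, np.zeros(shape, bool),
                          name="current_velocity", units="m/s")

    present = PredictorStack(
        {"bathymetry": bathy, "slope": slope, "temperature": temperature,
         "salinity": salinity, "current_velocity": current},
        scenario="present",
    )

    # future scenario: climate layers perturbed, terrain untouched
    temp_f = temperature.with_values(temp + params.warming)
    sal_f = salinity.with_values(sal + 0.05 * params.warming)
    curr_f = current.with_values(curr * (1.0 - 0.02 * params.warming))
    future = PredictorStack(
        {"bathymetry": bathy, "slope": slope, "temperature": temp_f,
         "salinity": sal_f, "current_velocity": curr_f},
        scenario="rcp85",
    )

    truth = _truth_layer(params, present)
    truth_future = _truth_layer(params, future)

    # patchy trawling effort concentrated on the 200-800 m band
    band = ((depth >= 200.0) & (depth <= 800.0)).astype(float)
    patches = _smooth_field(rng, shape, smoothness_cells)
    effort = np.where(patches > 0.2, np.exp(1.0 + 1.2 * patches), 0.0) * band
    fishing = RasterLayer(grid, effort, np.zeros(shape, bool),
                          name="fishing_effort", units="h/km2/yr")

    # three contiguous regional seas as longitude bands
    thirds = np.minimum(grid.n_cols - 1, np.arange(grid.n_cols) * 3 // grid.n_cols)
    regions = RasterLayer(
        grid, np.repeat(thirds[None, :] + 1, grid.n_rows, axis=0).astype(float),
        np.zeros(shape, bool), name="regions", units="label")

    return {"present": present, "future": future, "truth": truth,
            "truth_future": truth_future, "fishing": fishing, "regions": regions}


def _truth_layer(params: TruthParams, stack: PredictorStack) -> RasterLayer:
    mask = stack.combined_nodata()
    logit = truth_logit(
        params,
        depth_m=-stack["bathymetry"].values,
        slope_deg=np.where(stack["slope"].nodata, 0.0, stack["slope"].values),
        temp_c=stack["temperature"].values,
        sal_psu=stack["salinity"].values,
        curr_ms=stack["current_velocity"].values,
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    p[mask] = np.nan
    return RasterLayer(stack.grid, p, mask, name="truth", units="probability")


def sample_occurrences(truth: RasterLayer, bathymetry: RasterLayer,
                       design: SurveyDesign) -> pd.DataFrame:
    """Draw survey and presence-only occurrence records from the truth surface.

    Returns a DataFrame with columns ``lon, lat, detected, source, year``.
    """
    if truth.n_valid == 0:
        raise RasterError("truth surface is entirely nodata")
    grid = truth.grid
    rng = np.random.default_rng(design.seed)
    lon_g, lat_g = np.meshgrid(grid.lon_centers, grid.lat_centers)

    in_po = np.zeros(grid.shape, bool)
    for lo, la, lo2, la2 in design.presence_only_regions:
        in_po |= (lon_g >= lo) & (lon_g <= lo2) & (lat_g >= la) & (lat_g <= la2)

    depth = -bathymetry.values
    eligible = (~truth.nodata) & (~bathymetry.nodata) & (depth < design.max_survey_depth) & (~in_po)
    idx = np.flatnonzero(eligible)
    frames = []
    if design.n_survey_stations > 0:
        if idx.size == 0:
            raise RasterError("no eligible survey cells")
        pick = rng.choice(idx, size=design.n_survey_stations, replace=True)
        r, c = np.unravel_index(pick, grid.shape)
        p = truth.values[r, c]
        detected = rng.random(design.n_survey_stations) < p
        frames.append(pd.DataFrame({
            "lon": lon_g[r, c], "lat": lat_g[r, c],
            "detected": detected.astype(int), "source": "survey",
        }))
    if design.n_presence_only > 0:
        po_idx = np.flatnonzero(in_po & ~truth.nodata
                                & (depth < design.max_survey_depth))
        if po_idx.size == 0:
            raise RasterError("presence-only boxes contain no valid cells")
        w = truth.values.ravel()[po_idx]
        if w.sum() <= 0:
            w = np.ones_like(w)
        pick = rng.choice(po_idx, size=design.n_presence_only, replace=True,
                          p=w / w.sum())
        r, c = np.unravel_index(pick, grid.shape)
        frames.append(pd.DataFrame({
            "lon": lon_g[r, c], "lat": lat_g[r, c],
            "detected": 1, "source": "presence_only",
        }))
    if not frames:
        return pd.DataFrame(columns=["lon", "lat", "detected", "source", "year"])
    out = pd.concat(frames, ignore_index=True)
    out["year"] = 2000 + rng.integers(0, 21, size=len(out))
    return out
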