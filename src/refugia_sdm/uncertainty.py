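"""Uncertainty surfaces: calibration variability, algorithm disagreement and
kriging-based model-observation comparison.

Three complementary views of ensemble reliability:

* **calibration** — per-cell mean of the retained binary maps divided by
  their (population) standard deviation: an inverse coefficient of variation,
  high where the spatial-fold resamples agree;
* **algorithm disagreement** — the full ensemble methodology applied
  separately to the retained GAMs and the retained RFs, each sub-ensemble
  binarized with its own TSS-optimal threshold, then cross-tabulated;
* **kriged occurrence** — ordinary kriging of the survey presence/absence
  values (pseudo-absences excluded) restricted to a distance buffer around
  the stations, compared against the ensemble's binary prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .ensemble import ModelRun, ensemble_suitability, ensemble_threshold, _binarize
from .raster_core import GridSpec, RasterLayer, RasterError
from .spatial_cv import great_circle_km

logger = logging.getLogger(__name__)

# integer codes of the algorithm-disagreement map
DISAGREEMENT_CODES = {"both_unsuitable": 0, "gam_only": 1, "rf_only": 2,
                      "both_suitable": 3}
# integer codes of the model-observation agreement map
AGREEMENT_CODES = {"unsurveyed": 0, "agreement_suitable": 1,
                   "disagreement_suitable": 2, "agreement_unsuitable": 3,
                   "disagreement_unsuitable": 4}


class UncertaintyError(ValueError):
    pass


@dataclass
class VariogramModel:
    """Isotropic semivariogram: spherical or exponential, distances in km."""

    kind: str = "spherical"
    nugget: float = 0.0
    sill: float = 0.25
    range_km: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("spherical", "exponential"):
            raise UncertaintyError(f"unknown variogram kind {self.kind!r}")
        if self.nugget < 0 or self.sill <= 0 or self.range_km <= 0:
            raise UncertaintyError("variogram needs nugget >= 0, sill > 0, range > 0")
        if self.sill < self.nugget:
            raise UncertaintyError("sill must be >= nugget")

    def __call__(self, h) -> np.ndarray:
        """Semivariance gamma(h); gamma(0) = 0 by convention."""
        h = np.asarray(h, float)
        psill = self.sill - self.nugget
        if self.kind == "spherical":
            r = np.clip(h / self.range_km, 0.0, 1.0)
            g = self.nugget + psill * (1.5 * r - 0.5 * r ** 3)
        else:
            g = self.nugget + psill * (1.0 - np.exp(-3.0 * h / self.range_km))
        return np.where(h <= 0, 0.0, g)


# ---------------------------------------------------------------------------
# Calibration and algorithm disagreement
# ---------------------------------------------------------------------------

def calibration_uncertainty(retained: list[ModelRun], scenario: str) -> RasterLayer:
    """Per-cell mean/sd of the retained binary maps (population sd).

    Cells where all retained models agree (sd = 0) carry no ratio and are
    nodata; their count is stored in ``attrs`` of the returned layer name.
    """
    if len(retained) < 2:
        raise UncertaintyError("calibration uncertainty needs >= 2 retained runs")
    maps = [r.present_binary if scenario == "present" else r.future_binary
            for r in retained]
    stack = np.stack([m.masked() for m in maps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)  # population form (divisor n)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = mean / sd
    mask = ~np.isfinite(ratio)
    n_degenerate = int(np.sum((sd == 0) & np.isfinite(mean)))
    if n_degenerate:
        logger.info("calibration: %d cell(s) with zero spread set to nodata",
                    n_degenerate)
    ratio[mask] = np.nan
    return RasterLayer(maps[0].grid, ratio, mask,
                       name=f"calibration_{scenario}", units="mean/sd")


def algorithm_disagreement(retained: list[ModelRun], dataset: pd.DataFrame,
                           scenario: str) -> RasterLayer:
    """Cross-tabulation of the GAM-only and RF-only sub-ensembles.

    Each sub-ensemble is the mean of its retained binary maps, binarized with
    its own TSS-optimal threshold against the aggregated dataset.
    """
    by_algo = {}
    for algo in ("gam", "rf"):
        subset = [r for r in retained if r.algorithm == algo]
        if not subset:
            raise UncertaintyError(f"no retained {algo} runs")
        suit = ensemble_suitability(subset, scenario)
        suit_present = (suit if scenario == "present"
                        else ensemble_suitability(subset, "present"))
        thr = ensemble_threshold(suit_present, dataset)
        by_algo[algo] = _binarize(suit, thr)
    return disagreement_classes(by_algo["gam"], by_algo["rf"], scenario)


def disagreement_classes(gam_binary: RasterLayer, rf_binary: RasterLayer,
                         scenario: str = "present") -> RasterLayer:
    """Cross-tabulate two binary suitability maps into agreement classes."""
    g = gam_binary.masked()
    r = rf_binary.masked()
    code = np.full(g.shape, np.nan)
    code[(g == 0) & (r == 0)] = DISAGREEMENT_CODES["both_unsuitable"]
    code[(g == 1) & (r == 0)] = DISAGREEMENT_CODES["gam_only"]
    code[(g == 0) & (r == 1)] = DISAGREEMENT_CODES["rf_only"]
    code[(g == 1) & (r == 1)] = DISAGREEMENT_CODES["both_suitable"]
    mask = ~np.isfinite(code)
    return RasterLayer(gam_binary.grid, code, mask,
                       name=f"algorithm_disagreement_{scenario}", units="class")


# ---------------------------------------------------------------------------
# Ordinary kriging of presence/absence
# ---------------------------------------------------------------------------

def empirical_variogram(lon, lat, values, n_bins: int = 12,
                        max_dist_km: float | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram: (bin centers km, semivariance, n pairs)."""
    lon = np.asarray(lon, float); lat = np.asarray(lat, float)
    values = np.asarray(values, float)
    d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    iu = np.triu_indices(len(lon), k=1)
    h = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    g = sq[iu]
    if max_dist_km is None:
        max_dist_km = h.max() / 2
    edges = np.linspace(0, max_dist_km, n_bins + 1)
    which = np.digitize(h, edges) - 1
    centers, gamma, counts = [], [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        centers.append(h[sel].mean())
        gamma.append(g[sel].mean())
        counts.append(int(sel.sum()))
    return np.array(centers), np.array(gamma), np.array(counts)


def fit_variogram(lon, lat, values, kind: str = "spherical",
                  n_bins: int = 12) -> VariogramModel:
    """Weighted least-squares fit of a variogram model to the empirical cloud.

    Bins are weighted by their pair counts (Cressie-style), which down-weights
    the sparse long-distance bins.
    """
    h, g, n = empirical_variogram(lon, lat, values, n_bins=n_bins)
    if len(h) < 3:
        raise UncertaintyError("too few variogram bins to fit a model")
    w = np.sqrt(n)
    var = np.var(np.asarray(values, float))
    x0 = np.array([0.1 * max(var, 1e-6), max(var, 1e-6), max(h.max() / 2, 1.0)])

    def resid(p):
        nugget, psill, rng_ = np.abs(p)
        vm = VariogramModel(kind=kind, nugget=nugget, sill=nugget + psill + 1e-12,
                            range_km=max(rng_, 1e-6))
        return w * (vm(h) - g)

    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    nugget, psill, rng_ = np.abs(sol.x)
    return VariogramModel(kind=kind, nugget=float(nugget),
                          sill=float(nugget + psill + 1e-12),
                          range_km=float(max(rng_, 1e-6)))


def _ok_system(lon, lat, values, variogram: VariogramModel):
    """Assemble and factor the ordinary-kriging system (duplicates averaged)."""
    df = pd.DataFrame({"lon": lon, "lat": lat, "v": values})
    df = df.groupby(["lon", "lat"], as_index=False, sort=False)["v"].mean()
    lon = df["lon"].to_numpy(); lat = df["lat"].to_numpy()
    v = df["v"].to_numpy()
    n = len(df)
    if n < 3:
        raise UncertaintyError("ordinary kriging needs >= 3 distinct stations")
    d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram(d)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    # tiny jitter keeps the system well-posed when the nugget is 0
    A[:n, :n] += 1e-10 * np.eye(n)
    return lon, lat, v, A


def kriging_weights(lon, lat, values, variogram: VariogramModel,
                    pred_lon, pred_lat) -> np.ndarray:
    """OK weights for each prediction point (rows sum to 1)."""
    slon, slat, _, A = _ok_system(lon, lat, values, variogram)
    n = len(slon)
    pred_lon = np.atleast_1d(np.asarray(pred_lon, float))
    pred_lat = np.atleast_1d(np.asarray(pred_lat, float))
    d0 = great_circle_km(pred_lon[:, None], pred_lat[:, None],
                         slon[None, :], slat[None, :])
    B = np.empty((n + 1, len(pred_lon)))
    B[:n] = variogram(d0).T
    B[n] = 1.0
    sol = np.linalg.solve(A, B)
    return sol[:n].T


def krige_occurrence(records: pd.DataFrame, variogram: VariogramModel,
                     grid: GridSpec, buffer_km: float = 20.0) -> RasterLayer:
    """Ordinary kriging of the 0/1 ``detected`` values onto the grid.

    Prediction is confined to cells within ``buffer_km`` of at least one
    station; everything beyond the buffer is nodata.  Pseudo-absences must be
    excluded by the caller (pass survey records only).
    """
    if "source" in records.columns and (records["source"] == "pseudo_absence").any():
        raise UncertaintyError("kriging input must not contain pseudo-absences")
    slon, slat, v, A = _ok_system(records["lon"].to_numpy(),
                                  records["lat"].to_numpy(),
                                  records["detected"].to_numpy(float), variogram)
    n = len(slon)
    lon_g, lat_g = np.meshgrid(grid.lon_centers, grid.lat_centers)
    d0 = great_circle_km(lon_g.ravel()[:, None], lat_g.ravel()[:, None],
                         slon[None, :], slat[None, :])
    within = d0.min(axis=1) <= buffer_km
    B = np.empty((n + 1, int(within.sum())))
    B[:n] = variogram(d0[within]).T
    B[n] = 1.0
    w = np.linalg.solve(A, B)[:n]
    pred = v @ w
    values = np.full(grid.shape[0] * grid.shape[1], np.nan)
    values[within] = pred
    values = values.reshape(grid.shape)
    mask = ~np.isfinite(values)
    return RasterLayer(grid, values, mask, name="kriged_occurrence",
                       units="probability")


def observation_agreement(ensemble_binary: RasterLayer, kriged: RasterLayer,
                          occ_threshold: float = 0.5) -> RasterLayer:
    """Model vs interpolated-observation classes within the surveyed footprint.

    Outside the kriging buffer the class is ``unsurveyed``.
    """
    if ensemble_binary.grid != kriged.grid:
        raise RasterError("ensemble and kriged layers are on different grids")
    model = ensemble_binary.masked()
    occ = kriged.masked()
    code = np.full(model.shape, np.nan)
    surveyed = np.isfinite(occ) & np.isfinite(model)
    occ_pos = occ >= occ_threshold
    code[np.isfinite(model) & ~np.isfinite(occ)] = AGREEMENT_CODES["unsurveyed"]
    code[surveyed & (model == 1) & occ_pos] = AGREEMENT_CODES["agreement_suitable"]
    code[surveyed & (model == 1) & ~occ_pos] = AGREEMENT_CODES["disagreement_suitable"]
    code[surveyed & (model == 0) & ~occ_pos] = AGREEMENT_CODES["agreement_unsuitable"]
    code[surveyed & (model == 0) & occ_pos] = AGREEMENT_CODES["disagreement_unsuitable"]
    mask = ~np.isfinite(code)
    return RasterLayer(ensemble_binary.grid, code, mask,
                       name="observation_agreement", units="class")
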