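"""Trawling-effort risk classes and overlays with habitat surfaces.

Fishing effort (AIS hours km⁻² yr⁻¹) is discretized into four risk levels at
the quartiles of the *positive*-effort cells — zero-effort cells form their
own ``no_effort`` class.  Risk maps are then overlaid with binary target
surfaces (observed-presence footprint, presently suitable habitat, climate
refugia) and summarized as km² per region and risk level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_core import RasterLayer, RasterError, cell_area

RISK_CODES = {"no_effort": 0, "low": 1, "medium": 2, "high": 3, "very_high": 4}
RISK_CLASSES = ("no_effort", "low", "medium", "high", "very_high")


class FishingRiskError(ValueError):
    pass


@dataclass
class RiskMap:
    classes: RasterLayer
    edges_hours: tuple[float, float, float]   # Q1, Q2, Q3 of positive effort

    def class_mask(self, name: str) -> np.ndarray:
        return (~self.classes.nodata) & (self.classes.values == RISK_CODES[name])


def risk_levels(fishing: RasterLayer) -> RiskMap:
    """Quartile-based effort classes over positive-effort cells.

    Classes: low (0, Q1], medium (Q1, Q2], high (Q2, Q3], very_high (> Q3);
    zero effort is its own class.  Quantiles use the linear-interpolation
    convention.
    """
    eff = fishing.masked()
    if np.nanmin(eff) < 0:
        raise FishingRiskError("fishing effort must be >= 0")
    pos = eff[np.isfinite(eff) & (eff > 0)]
    if pos.size < 4:
        raise FishingRiskError("need at least 4 positive-effort cells for quartiles")
    q1, q2, q3 = np.quantile(pos, [0.25, 0.5, 0.75])
    code = np.full(eff.shape, np.nan)
    valid = np.isfinite(eff)
    code[valid & (eff == 0)] = RISK_CODES["no_effort"]
    code[valid & (eff > 0) & (eff <= q1)] = RISK_CODES["low"]
    code[valid & (eff > q1) & (eff <= q2)] = RISK_CODES["medium"]
    code[valid & (eff > q2) & (eff <= q3)] = RISK_CODES["high"]
    code[valid & (eff > q3)] = RISK_CODES["very_high"]
    mask = ~np.isfinite(code)
    return RiskMap(
        classes=RasterLayer(fishing.grid, code, mask, name="fishing_risk",
                            units="class"),
        edges_hours=(float(q1), float(q2), float(q3)),
    )


def overlay_risk(risk: RiskMap, target: RasterLayer,
                 regions: RasterLayer, target_name: str = "target") -> pd.DataFrame:
    """km² of target-positive cells per (region, risk class), plus basin rows.

    ``target`` must be a binary 0/1 layer (e.g. a suitability or refugia
    mask); nodata target cells contribute nothing.
    """
    grid = risk.classes.grid
    if target.grid != grid or regions.grid != grid:
        raise RasterError("risk, target and regions must share one grid")
    tvals = target.masked()
    tv = tvals[np.isfinite(tvals)]
    if not np.isin(tv, (0.0, 1.0)).all():
        raise FishingRiskError("overlay target must be binary 0/1")
    area = cell_area(grid).values
    positive = np.isfinite(tvals) & (tvals == 1)
    rows = []
    region_vals = regions.masked()
    labels = np.unique(region_vals[np.isfinite(region_vals)]).astype(int)
    for cls in RISK_CLASSES:
        in_cls = risk.class_mask(cls)
        for lab in labels:
            sel = positive & in_cls & (region_vals == lab)
            rows.append({"region": str(lab), "risk_class": cls,
                         "target": target_name,
                         "area_km2": float(area[sel].sum()),
                         "n_cells": int(sel.sum())})
        sel = positive & in_cls
        rows.append({"region": "basin", "risk_class": cls,
                     "target": target_name,
                     "area_km2": float(area[sel].sum()),
                     "n_cells": int(sel.sum())})
    return pd.DataFrame(rows)
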