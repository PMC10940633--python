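"""Habitat-change classification between present and future scenarios.

Both ensemble suitability surfaces are binarized with the single ensemble
threshold and combined cell-wise into four classes: *refugia* (suitable now
and in 2100), *loss* (suitable now only), *gain* (suitable in 2100 only) and
*absence* (never suitable).  Headline statistics are expressed relative to
the presently suitable area: ``loss_pct = area(loss) / (area(loss) +
area(refugia)) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_core import RasterLayer, RasterError, cell_area

CHANGE_CODES = {"absence": 0, "gain": 1, "loss": 2, "refugia": 3}


class ChangeError(ValueError):
    pass


@dataclass
class ChangeMap:
    classes: RasterLayer            # integer-coded categorical layer
    areas_km2: dict[str, float]     # per-class surface
    cell_counts: dict[str, int]

    def class_mask(self, name: str) -> np.ndarray:
        code = CHANGE_CODES[name]
        return (~self.classes.nodata) & (self.classes.values == code)


def binarize_ensemble(suitability: RasterLayer, threshold: float) -> RasterLayer:
    """1 iff suitability >= threshold; nodata propagated."""
    if not 0.0 <= threshold <= 1.0:
        raise ChangeError(f"threshold {threshold} outside [0, 1]")
    values = np.where(suitability.values >= threshold, 1.0, 0.0)
    values[suitability.nodata] = np.nan
    return suitability.with_values(values, name=suitability.name + "_binary",
                                   units="0/1")


def apply_depth_mask(layer: RasterLayer, bathymetry: RasterLayer,
                     max_depth: float = 2000.0) -> RasterLayer:
    """Restrict a layer to the study area (cells no deeper than max_depth)."""
    if layer.grid != bathymetry.grid:
        raise RasterError("depth mask grid mismatch")
    deep = (-bathymetry.values > max_depth) | bathymetry.nodata
    values = layer.values.copy()
    values[deep] = np.nan
    return layer.with_values(values, nodata=layer.nodata | deep)


def classify_change(present_binary: RasterLayer,
                    future_binary: RasterLayer) -> ChangeMap:
    """Combine two binary maps into the four-class change map."""
    if present_binary.grid != future_binary.grid:
        raise RasterError("present and future binary maps on different grids")
    p = present_binary.masked()
    f = future_binary.masked()
    for arr, which in ((p, "present"), (f, "future")):
        vals = arr[np.isfinite(arr)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ChangeError(f"{which} map is not binary")
    code = np.full(p.shape, np.nan)
    both = np.isfinite(p) & np.isfinite(f)
    code[both & (p == 1) & (f == 1)] = CHANGE_CODES["refugia"]
    code[both & (p == 1) & (f == 0)] = CHANGE_CODES["loss"]
    code[both & (p == 0) & (f == 1)] = CHANGE_CODES["gain"]
    code[both & (p == 0) & (f == 0)] = CHANGE_CODES["absence"]
    mask = ~np.isfinite(code)
    classes = RasterLayer(present_binary.grid, code, mask,
                          name="habitat_change", units="class")
    area = cell_area(present_binary.grid).values
    areas, counts = {}, {}
    for name, c in CHANGE_CODES.items():
        sel = (~mask) & (code == c)
        areas[name] = float(area[sel].sum())
        counts[name] = int(sel.sum())
    return ChangeMap(classes=classes, areas_km2=areas, cell_counts=counts)


def habitat_change_summary(change: ChangeMap) -> dict:
    """Loss/gain/refugia statistics relative to the presently suitable area.

    Both area-weighted (primary) and cell-counted percentages are reported.
    """
    a = change.areas_km2
    present_suitable = a["loss"] + a["refugia"]
    if present_suitable <= 0:
        raise ChangeError("no presently suitable area; percentages undefined")
    n = change.cell_counts
    present_cells = n["loss"] + n["refugia"]
    return {
        "loss_pct": 100.0 * a["loss"] / present_suitable,
        "gain_pct": 100.0 * a["gain"] / present_suitable,
        "refugia_pct": 100.0 * a["refugia"] / present_suitable,
        "loss_pct_cells": 100.0 * n["loss"] / present_cells,
        "gain_pct_cells": 100.0 * n["gain"] / present_cells,
        "present_suitable_km2": present_suitable,
        "future_suitable_km2": a["gain"] + a["refugia"],
        "areas_km2": dict(a),
        "cell_counts": dict(n),
    }


def truth_level_loss_pct(truth_present: RasterLayer, truth_future: RasterLayer,
                         threshold: float = 0.5) -> float:
    """Loss percentage computed directly on generator truth surfaces.

    Used to check that estimated loss tracks the generating process without
    any model in between.
    """
    change = classify_change(binarize_ensemble(truth_present, threshold),
                             binarize_ensemble(truth_future, threshold))
    return habitat_change_summary(change)["loss_pct"]


def change_summary_frame(change: ChangeMap) -> pd.DataFrame:
    return pd.DataFrame({
        "class": list(CHANGE_CODES),
        "area_km2": [change.areas_km2[c] for c in CHANGE_CODES],
        "n_cells": [change.cell_counts[c] for c in CHANGE_CODES],
    })
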