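"""Occurrence-record preparation: pseudo-absences, grid aggregation, extraction.

The raw record table mixes survey stations (presence *and* absence) with
presence-only sources (ROV dives, literature).  Presence-only zones would
otherwise bias a presence-absence model, so pseudo-absences are implanted in
those zones at the survey presence/absence ratio.  Records are then thinned to
one per grid cell (presences take priority) and annotated with the predictor
values of their cell.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .raster_core import GridSpec, PredictorStack, RasterLayer, RasterError

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["lon", "lat", "detected", "source", "year"]


class DataPrepError(ValueError):
    pass


def add_pseudo_absences(records: pd.DataFrame,
                        presence_only_regions: list[tuple[float, float, float, float]],
                        bathymetry: RasterLayer,
                        seed: int = 0,
                        max_depth: float = 1000.0) -> pd.DataFrame:
    """Implant pseudo-absence records inside each presence-only box.

    For every box, ``round(n_presences_in_box * survey_absences /
    survey_presences)`` pseudo-absences are placed at uniformly random cell
    centers inside the box, excluding cells deeper than ``max_depth`` and
    cells already holding any record.  No pseudo-absences are added outside
    the boxes (survey absences cover those areas).
    """
    survey = records[records["source"] == "survey"]
    n_pres = int((survey["detected"] == 1).sum())
    n_abs = int((survey["detected"] == 0).sum())
    if n_pres == 0:
        raise DataPrepError("no survey presences: presence/absence ratio undefined")
    if not presence_only_regions:
        return records.copy()
    ratio = n_abs / n_pres

    grid = bathymetry.grid
    lon_g, lat_g = np.meshgrid(grid.lon_centers, grid.lat_centers)
    depth = -bathymetry.values
    occupied = np.zeros(grid.shape, bool)
    row, col = grid.cell_of(records["lon"].to_numpy(), records["lat"].to_numpy())
    occupied[row, col] = True

    rng = np.random.default_rng(seed)
    added = []
    for box in presence_only_regions:
        lo, la, lo2, la2 = box
        in_box = (lon_g >= lo) & (lon_g <= lo2) & (lat_g >= la) & (lat_g <= la2)
        rec_in_box = ((records["lon"] >= lo) & (records["lon"] <= lo2)
                      & (records["lat"] >= la) & (records["lat"] <= la2))
        n_box_pres = int((records.loc[rec_in_box, "detected"] == 1).sum())
        n_pa = int(round(n_box_pres * ratio))
        if n_pa == 0:
            continue
        eligible = in_box & (~bathymetry.nodata) & (depth <= max_depth) & (~occupied)
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            logger.warning("presence-only box %s has no eligible cells; 0 pseudo-absences", box)
            continue
        take = min(n_pa, idx.size)
        if take < n_pa:
            logger.warning("box %s: only %d eligible cells for %d pseudo-absences",
                           box, idx.size, n_pa)
        pick = rng.choice(idx, size=take, replace=False)
        r, c = np.unravel_index(pick, grid.shape)
        occupied[r, c] = True
        added.append(pd.DataFrame({
            "lon": lon_g[r, c], "lat": lat_g[r, c], "detected": 0,
            "source": "pseudo_absence", "year": pd.NA,
        }))
    if not added:
        return records.copy()
    out = pd.concat([records] + added, ignore_index=True)
    logger.info("added %d pseudo-absences (survey ratio %.3f absences/presence)",
                len(out) - len(records), ratio)
    return out


def aggregate_to_grid(records: pd.DataFrame, grid: GridSpec, seed: int = 0) -> pd.DataFrame:
    """Keep one record per occupied grid cell, presences taking priority.

    If a cell holds at least one presence, a uniformly random presence is
    kept; otherwise a uniformly random absence.  Output rows carry ``row``
    and ``col`` cell indices and the cell-center coordinates.
    """
    if len(records) == 0:
        raise DataPrepError("cannot aggregate an empty record table")
    rng = np.random.default_rng(seed)
    df = records.copy().reset_index(drop=True)
    row, col = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    df["row"], df["col"] = row, col
    # random priority within (cell, detected) groups, presences first
    df["_rand"] = rng.random(len(df))
    df = df.sort_values(["row", "col", "detected", "_rand"],
                        ascending=[True, True, False, True], kind="mergesort")
    out = df.drop_duplicates(subset=["row", "col"], keep="first")
    out = out.drop(columns=["_rand"]).sort_values(["row", "col"], kind="mergesort")
    lon_c, lat_c = grid.center_of(out["row"].to_numpy(), out["col"].to_numpy())
    out["lon"], out["lat"] = lon_c, lat_c
    cols = ["lon", "lat", "detected", "source", "year", "row", "col"]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra].reset_index(drop=True)


def extract_predictors(dataset: pd.DataFrame, stack: PredictorStack) -> pd.DataFrame:
    """Annotate each aggregated record with its cell's predictor values.

    Records falling on any nodata predictor cell are dropped; the dropped
    count is logged and stored in ``DataFrame.attrs['n_dropped_nodata']``.
    """
    grid = stack.grid
    if "row" in dataset.columns:
        row = dataset["row"].to_numpy()
        col = dataset["col"].to_numpy()
        if row.max(initial=0) >= grid.n_rows or col.max(initial=0) >= grid.n_cols:
            raise RasterError("dataset cell indices do not fit the stack grid")
    else:
        row, col = grid.cell_of(dataset["lon"].to_numpy(), dataset["lat"].to_numpy())
    out = dataset.copy().reset_index(drop=True)
    keep = np.ones(len(out), bool)
    for name, layer in stack.layers.items():
        out[name] = layer.values[row, col]
        keep &= ~layer.nodata[row, col]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d record(s) on nodata predictor cells", n_dropped)
    out = out[keep].reset_index(drop=True)
    out.attrs["n_dropped_nodata"] = n_dropped
    return out
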