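"""Spatial block construction and repeated random fold assignment.

Occurrence data are spatially autocorrelated, so random record-level CV
leaks information between train and test splits.  Records are instead tiled
into square blocks of a fixed side (default 250 km) and whole blocks are
dealt to folds, so held-out records are geographically separated from the
training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: km per degree of latitude on the reference ellipsoid quadrant.
KM_PER_DEG_LAT = 111.19


class SpatialCVError(ValueError):
    pass


@dataclass
class FoldAssignment:
    """Record -> (block, fold) mapping for one CV repeat."""

    repeat_id: int
    n_folds: int
    block_of_record: np.ndarray   # int per record
    fold_of_record: np.ndarray    # int in 1..n_folds per record

    def __post_init__(self) -> None:
        self.block_of_record = np.asarray(self.block_of_record, dtype=int)
        self.fold_of_record = np.asarray(self.fold_of_record, dtype=int)
        if self.block_of_record.shape != self.fold_of_record.shape:
            raise SpatialCVError("block and fold arrays differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "record": np.arange(len(self.fold_of_record)),
            "repeat": self.repeat_id,
            "block": self.block_of_record,
            "fold": self.fold_of_record,
        })


def build_blocks(dataset: pd.DataFrame, block_size_km: float = 250.0) -> np.ndarray:
    """Label each record with the id of its checkerboard tile.

    The tile side is converted from km to degrees using 1 deg latitude =
    111.19 km and 1 deg longitude = 111.19 * cos(mean latitude) km, since the
    block size is stated in km on an unprojected lon/lat grid.
    """
    if len(dataset) == 0:
        raise SpatialCVError("cannot build blocks for an empty dataset")
    if block_size_km <= 0:
        raise SpatialCVError("block_size_km must be > 0")
    lon = dataset["lon"].to_numpy(float)
    lat = dataset["lat"].to_numpy(float)
    mean_lat = lat.mean()
    tile_deg_lat = block_size_km / KM_PER_DEG_LAT
    tile_deg_lon = block_size_km / (KM_PER_DEG_LAT * np.cos(np.radians(mean_lat)))
    ix = np.floor((lon - lon.min()) / tile_deg_lon).astype(int)
    iy = np.floor((lat - lat.min()) / tile_deg_lat).astype(int)
    return ix * (iy.max() + 1) + iy


def assign_folds(blocks: np.ndarray, n_folds: int = 5, seed: int = 0,
                 repeat_id: int = 1) -> FoldAssignment:
    """Deal occupied blocks round-robin to folds after a seeded shuffle.

    Round-robin dealing balances block counts across folds (sizes differ by
    at most one block) and guarantees every fold is non-empty.
    """
    blocks = np.asarray(blocks, dtype=int)
    occupied = np.unique(blocks)
    if occupied.size < n_folds:
        raise SpatialCVError(
            f"{occupied.size} occupied blocks < {n_folds} folds; "
            "enlarge the extent or reduce block size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(occupied)
    fold_of_block = {int(b): (i % n_folds) + 1 for i, b in enumerate(order)}
    folds = np.array([fold_of_block[int(b)] for b in blocks])
    return FoldAssignment(repeat_id=repeat_id, n_folds=n_folds,
                          block_of_record=blocks, fold_of_record=folds)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km (broadcasting inputs)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float),
                                              np.asarray(lat1, float),
                                              np.asarray(lon2, float),
                                              np.asarray(lat2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
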