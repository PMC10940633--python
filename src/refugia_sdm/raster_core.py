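"""Grid/raster data model, GeoTIFF I/O, resampling, terrain and area accounting.

All spatial computation in the package happens on :class:`RasterLayer` objects:
a single gridded variable on a geographic (lon/lat, EPSG:4326-equivalent)
grid with cell-center registration.  Row 0 is the **northernmost** row and
column 0 the westernmost column; ``lon_min``/``lat_min`` are the *centers* of
the south-west cell.  Nodata is carried as an explicit boolean mask and is
propagated conservatively: any operation consuming a nodata cell emits nodata
rather than imputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy.interpolate import RegularGridInterpolator

#: Mean Earth radius used for all degree->meter conversions (m).
EARTH_RADIUS_M = 6_371_000.0
EARTH_RADIUS_KM = EARTH_RADIUS_M / 1000.0

# GeoTIFF / GDAL private tags
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

_GEOGRAPHIC_MODEL_TYPE = 2  # GTModelTypeGeoKey: ModelTypeGeographic
_PROJECTED_MODEL_TYPE = 1


class RasterError(ValueError):
    """Raised on contract violations in raster operations."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid with cell-center registration.

    Parameters
    ----------
    lon_min, lat_min
        Center coordinates (decimal degrees) of the south-west cell.
    cell_size
        Cell side in decimal degrees (square cells).
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    """

    lon_min: float
    lat_min: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise RasterError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise RasterError("grid must have at least one row and column")

    # -- coordinate helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_max(self) -> float:
        """Center latitude of the northernmost row."""
        return self.lat_min + (self.n_rows - 1) * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + (self.n_cols - 1) * self.cell_size

    @property
    def lon_centers(self) -> np.ndarray:
        """West->east cell-center longitudes (length n_cols)."""
        return self.lon_min + self.cell_size * np.arange(self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        """North->south cell-center latitudes, matching row order."""
        return self.lat_max - self.cell_size * np.arange(self.n_rows)

    def center_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) centers for (arrays of) row/col indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon_min + col * self.cell_size
        lat = self.lat_max - row * self.cell_size
        return lon, lat

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell whose footprint contains each point.

        Raises :class:`RasterError` if any point lies outside the grid
        footprint (outer cell edges).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - (self.lon_min - self.cell_size / 2)) / self.cell_size)
        row = np.floor(((self.lat_max + self.cell_size / 2) - lat) / self.cell_size)
        # points exactly on the outer east/north edge belong to the last cell
        col = np.where(col == self.n_cols, self.n_cols - 1, col)
        row = np.where(row == self.n_rows, self.n_rows - 1, row)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            raise RasterError(f"{int(np.sum(bad))} point(s) outside the grid extent")
        return row.astype(int), col.astype(int)

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        h = self.cell_size / 2
        return (
            (lon >= self.lon_min - h)
            & (lon <= self.lon_max + h)
            & (lat >= self.lat_min - h)
            & (lat <= self.lat_max + h)
        )


@dataclass
class RasterLayer:
    """One gridded variable plus its nodata mask.

    ``nodata`` is True where the cell carries no value; ``values`` must be
    finite wherever ``nodata`` is False.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: np.ndarray = None  # type: ignore[assignment]
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise RasterError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.nodata is None:
            self.nodata = ~np.isfinite(self.values)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        if self.nodata.shape != self.grid.shape:
            raise RasterError("nodata mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata])):
            raise RasterError(f"non-finite values outside the nodata mask in {self.name!r}")

    def with_values(self, values: np.ndarray, nodata: np.ndarray | None = None,
                    name: str | None = None, units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            grid=self.grid,
            values=values,
            nodata=self.nodata.copy() if nodata is None else nodata,
            name=self.name if name is None else name,
            units=self.units if units is None else units,
        )

    def masked(self) -> np.ndarray:
        """Values with nodata cells replaced by NaN."""
        out = self.values.astype(float).copy()
        out[self.nodata] = np.nan
        return out

    @property
    def n_valid(self) -> int:
        return int(np.sum(~self.nodata))

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.nodata.copy(),
                           self.name, self.units)


@dataclass
class PredictorStack:
    """Named set of co-registered predictor layers for one scenario."""

    layers: dict[str, RasterLayer]
    scenario: str = "present"

    def __post_init__(self) -> None:
        grids = {id(l.grid) for l in self.layers.values()}
        ref = self.grid
        for name, layer in self.layers.items():
            if layer.grid != ref:
                raise RasterError(f"layer {name!r} is not on the shared grid")

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        return self.layers[name]

    def combined_nodata(self) -> np.ndarray:
        """True where *any* layer is nodata."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            mask |= layer.nodata
        return mask


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_layer(layer: RasterLayer, target: GridSpec, direction: str) -> RasterLayer:
    """Bring a layer onto ``target``.

    ``mean_downscale`` averages all source cells whose centers fall inside a
    target cell (ignoring nodata); it requires the target resolution to be
    coarser than or equal to the source.  ``bilinear_upscale`` interpolates
    from the four surrounding source cell centers and requires the target to
    be finer than or equal to the source.  Target cells with no contributing
    data are nodata.
    """
    if direction not in ("mean_downscale", "bilinear_upscale"):
        raise RasterError(f"unknown resampling direction {direction!r}")
    src = layer.grid
    tol = 1e-9
    if direction == "mean_downscale" and target.cell_size < src.cell_size - tol:
        raise RasterError("mean_downscale requires target cell_size >= source cell_size")
    if direction == "bilinear_upscale" and target.cell_size > src.cell_size + tol:
        raise RasterError("bilinear_upscale requires target cell_size <= source cell_size")

    if direction == "mean_downscale":
        out = _mean_downscale(layer, target)
    else:
        out = _bilinear_upscale(layer, target)
    if out.n_valid == 0 and layer.n_valid > 0:
        raise RasterError("empty overlap between source and target grids")
    return out


def _mean_downscale(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    src = layer.grid
    lon, lat = np.meshgrid(src.lon_centers, src.lat_centers)
    valid = ~layer.nodata
    inside = target.contains(lon, lat) & valid
    if not np.any(inside):
        raise RasterError("empty overlap between source and target grids")
    row, col = target.cell_of(lon[inside], lat[inside])
    sums = np.zeros(target.shape)
    counts = np.zeros(target.shape)
    np.add.at(sums, (row, col), layer.values[inside])
    np.add.at(counts, (row, col), 1.0)
    with np.errstate(invalid="ignore"):
        values = sums / counts
    mask = counts == 0
    values[mask] = np.nan
    return RasterLayer(target, values, mask, layer.name, layer.units)


def _bilinear_upscale(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    src = layer.grid
    # ascending axes for the interpolator; NaN at nodata poisons any target
    # cell drawing on a missing source neighbor (conservative propagation)
    lat_asc = src.lat_centers[::-1]
    z = layer.masked()[::-1, :]
    if src.n_rows == 1 or src.n_cols == 1:
        raise RasterError("bilinear_upscale needs at least a 2x2 source grid")
    interp = RegularGridInterpolator(
        (lat_asc, src.lon_centers), z, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    lon, lat = np.meshgrid(target.lon_centers, target.lat_centers)
    values = interp(np.column_stack([lat.ravel(), lon.ravel()])).reshape(target.shape)
    mask = ~np.isfinite(values)
    return RasterLayer(target, values, mask, layer.name, layer.units)


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

def horn_slope(bathymetry: RasterLayer) -> RasterLayer:
    """Seafloor slope (degrees) by Horn's 1-2-1 weighted eight-neighbor method.

    The horizontal step is converted from degrees to meters with a spherical
    Earth of radius 6371 km; the east-west step shrinks with ``cos(latitude)``
    per row.  Border cells and cells with any nodata neighbor are nodata.
    """
    grid = bathymetry.grid
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise RasterError("horn_slope needs a raster of at least 3x3 cells")
    z = bathymetry.masked()
    deg = np.pi / 180.0
    dy = grid.cell_size * deg * EARTH_RADIUS_M
    dx_row = grid.cell_size * deg * EARTH_RADIUS_M * np.cos(grid.lat_centers * deg)

    # 3x3 window around each interior cell; rows run north->south
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx_row[1:-1, None])
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * dy)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    values = np.full(grid.shape, np.nan)
    values[1:-1, 1:-1] = slope
    values[bathymetry.nodata] = np.nan  # the center cell itself is unusable
    mask = ~np.isfinite(values)
    return RasterLayer(grid, values, mask, name="slope", units="degrees")


def cell_area(grid: GridSpec) -> RasterLayer:
    """Per-cell surface area in km² on a spherical Earth.

    ``A = R² · Δλ · (sin φ_top − sin φ_bottom)`` with R = 6371 km; constant
    along a row and shrinking toward the poles.
    """
    deg = np.pi / 180.0
    half = grid.cell_size / 2.0
    lat = grid.lat_centers
    band = np.sin((lat + half) * deg) - np.sin((lat - half) * deg)
    area_row = EARTH_RADIUS_KM ** 2 * (grid.cell_size * deg) * band
    values = np.repeat(area_row[:, None], grid.n_cols, axis=1)
    return RasterLayer(grid, values, np.zeros(grid.shape, bool),
                       name="cell_area", units="km2")


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(layer: RasterLayer, path, nodata_value: float = -9999.0) -> None:
    """Write a single-band float32 GeoTIFF with geographic CRS tags.

    Nodata cells are stored as ``nodata_value`` and declared in the
    ``GDAL_NODATA`` tag; the grid geometry is stored in the standard
    pixel-scale/tiepoint tags (area registration, tiepoint at the outer
    north-west corner).
    """
    grid = layer.grid
    data = layer.values.astype(np.float32)
    data[layer.nodata] = np.float32(nodata_value)
    cs = float(grid.cell_size)
    west_edge = grid.lon_min - cs / 2
    north_edge = grid.lat_max + cs / 2
    geokeys = (
        1, 1, 0, 3,                      # version, revision, minor, key count
        1024, 0, 1, _GEOGRAPHIC_MODEL_TYPE,  # GTModelTypeGeoKey
        1025, 0, 1, 1,                   # GTRasterTypeGeoKey: PixelIsArea
        2048, 0, 1, 4326,                # GeographicTypeGeoKey: WGS84
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west_edge, north_edge, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata_value)),
    ]
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)


def read_raster(path, name: str = "", units: str = "") -> RasterLayer:
    """Read a single-band geographic GeoTIFF written by :func:`write_raster`.

    Raises :class:`RasterError` for multi-band files or projected CRSs.
    """
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise RasterError(f"{path}: expected a single band, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise RasterError(
                f"{path}: expected a single band, found {page.samplesperpixel} samples/pixel"
            )
        tags = page.tags
        if _TAG_GEO_KEY_DIRECTORY not in tags:
            raise RasterError(f"{path}: missing GeoTIFF key directory (not a GeoTIFF?)")
        keys = np.asarray(tags[_TAG_GEO_KEY_DIRECTORY].value).reshape(-1, 4)
        model_type = None
        for key_id, _, _, value in keys[1:]:
            if key_id == 1024:
                model_type = int(value)
        if model_type == _PROJECTED_MODEL_TYPE:
            raise RasterError(f"{path}: projected CRS not supported; provide lon/lat rasters")
        if model_type != _GEOGRAPHIC_MODEL_TYPE:
            raise RasterError(f"{path}: could not identify a geographic CRS")
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterError(f"{path}: missing pixel scale / tiepoint tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-9:
            raise RasterError(f"{path}: non-square cells ({sx} x {sy}) not supported")
        tie = tags[_TAG_MODEL_TIEPOINT].value
        west_edge, north_edge = tie[3], tie[4]
        data = page.asarray().astype(float)
        n_rows, n_cols = data.shape
        grid = GridSpec(
            lon_min=west_edge + sx / 2,
            lat_min=north_edge - sy / 2 - (n_rows - 1) * sy,
            cell_size=float(sx),
            n_rows=n_rows,
            n_cols=n_cols,
        )
        mask = ~np.isfinite(data)
        if _TAG_GDAL_NODATA in tags:
            sentinel = float(tags[_TAG_GDAL_NODATA].value)
            mask |= data == sentinel
        data[mask] = np.nan
        return RasterLayer(grid, data, mask, name=name, units=units)
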