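"""Raster data model: resampling, Horn slope, spherical cell areas, GeoTIFF."""

import numpy as np
import pytest
from scipy.integrate import quad

from refugia_sdm.raster_core import (EARTH_RADIUS_KM, EARTH_RADIUS_M, GridSpec,
                                     RasterLayer, RasterError, cell_area,
                                     horn_slope, read_raster, resample_layer,
                                     write_raster)


def layer_from(values, lon_min=0.0, lat_min=0.0, cell=1.0, **kw):
    values = np.asarray(values, float)
    grid = GridSpec(lon_min, lat_min, cell, *values.shape)
    return RasterLayer(grid, values, **kw)


class TestGridSpec:
    def test_center_cell_roundtrip(self):
        grid = GridSpec(5.0, 40.0, 0.25, 7, 9)
        rows, cols = np.meshgrid(np.arange(7), np.arange(9), indexing="ij")
        lon, lat = grid.center_of(rows.ravel(), cols.ravel())
        r2, c2 = grid.cell_of(lon, lat)
        assert np.array_equal(r2, rows.ravel())
        assert np.array_equal(c2, cols.ravel())

    def test_row_zero_is_northernmost(self):
        grid = GridSpec(0.0, 30.0, 0.5, 4, 4)
        _, lat_top = grid.center_of(0, 0)
        _, lat_bottom = grid.center_of(3, 0)
        assert lat_top > lat_bottom

    @pytest.mark.parametrize("kwargs", [
        dict(lon_min=0, lat_min=0, cell_size=0.0, n_rows=2, n_cols=2),
        dict(lon_min=0, lat_min=0, cell_size=1.0, n_rows=0, n_cols=2),
    ])
    def test_invalid_grid_rejected(self, kwargs):
        with pytest.raises(RasterError):
            GridSpec(**kwargs)


class TestResample:
    def test_constant_preserved_both_directions(self):
        src = layer_from(np.full((4, 4), 7.0))
        down = resample_layer(src, GridSpec(0.0, 0.0, 2.0, 2, 2), "mean_downscale")
        assert np.allclose(down.values, 7.0)
        up = resample_layer(src, GridSpec(0.25, 0.25, 0.5, 7, 7), "bilinear_upscale")
        assert np.allclose(up.values[~up.nodata], 7.0)

    def test_mean_downscale_2x2_to_1x1(self):
        src = layer_from([[0.0, 2.0], [4.0, 6.0]])
        target = GridSpec(0.5, 0.5, 2.0, 1, 1)
        out = resample_layer(src, target, "mean_downscale")
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_bilinear_midpoint_of_four_centers(self):
        # centers at lon/lat {0,1}x{0,1}; midpoint (0.5, 0.5) averages all 4
        src = layer_from([[0.0, 1.0], [1.0, 2.0]])
        target = GridSpec(0.5, 0.5, 1.0, 1, 1)
        out = resample_layer(src, target, "bilinear_upscale")
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_identity_on_same_grid(self, rng):
        src = layer_from(rng.normal(size=(5, 6)))
        for direction in ("mean_downscale", "bilinear_upscale"):
            out = resample_layer(src, src.grid, direction)
            assert np.allclose(out.values[~out.nodata],
                               src.values[~out.nodata])

    def test_mean_downscale_conserves_global_mean_on_nested_grid(self, rng):
        src = layer_from(rng.normal(size=(8, 8)), cell=0.5)
        target = GridSpec(0.25, 0.25, 1.0, 4, 4)  # exactly nests 2x2 source cells
        out = resample_layer(src, target, "mean_downscale")
        assert out.values.mean() == pytest.approx(src.values.mean(), abs=1e-12)

    def test_downscale_ignores_nodata_cells(self):
        vals = np.array([[1.0, np.nan], [3.0, 5.0]])
        src = layer_from(vals)
        out = resample_layer(src, GridSpec(0.5, 0.5, 2.0, 1, 1), "mean_downscale")
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_direction_inconsistent_with_resolution(self):
        src = layer_from(np.zeros((4, 4)))
        with pytest.raises(RasterError):
            resample_layer(src, GridSpec(0, 0, 0.5, 8, 8), "mean_downscale")
        with pytest.raises(RasterError):
            resample_layer(src, GridSpec(0, 0, 2.0, 2, 2), "bilinear_upscale")

    def test_empty_overlap_errors(self):
        src = layer_from(np.ones((3, 3)))
        far = GridSpec(100.0, 50.0, 1.0, 3, 3)
        with pytest.raises(RasterError, match="overlap"):
            resample_layer(src, far, "mean_downscale")


class TestHornSlope:
    def test_flat_raster_zero_slope(self):
        out = horn_slope(layer_from(np.full((5, 5), -500.0), cell=0.01))
        inner = out.values[1:-1, 1:-1]
        assert np.allclose(inner, 0.0)
        assert out.nodata[0].all() and out.nodata[-1].all()

    def test_planar_ramp_recovers_analytic_gradient(self):
        # z = a * x_meters with a = 0.1: Horn weights are exact on a plane
        grid = GridSpec(0.0, 45.0, 0.01, 7, 7)
        deg = np.pi / 180
        dx = grid.cell_size * deg * EARTH_RADIUS_M * np.cos(grid.lat_centers * deg)
        x_m = np.cumsum(np.broadcast_to(dx[:, None], (7, 7)), axis=1)
        layer = RasterLayer(grid, 0.1 * x_m)
        out = horn_slope(layer)
        expected = np.degrees(np.arctan(0.1))
        assert np.allclose(out.values[2:-2, 2:-2], expected, rtol=1e-6)

    def test_center_matches_hand_computed_window(self):
        # independent spreadsheet-style evaluation of Horn's formula
        z = np.array([[-100.0, -110.0, -95.0],
                      [-120.0, -105.0, -98.0],
                      [-130.0, -115.0, -107.0]])
        grid = GridSpec(0.0, 0.0, 0.01, 3, 3)
        deg = np.pi / 180
        dx = 0.01 * deg * EARTH_RADIUS_M * np.cos(0.01 * deg)  # center-row lat
        dy = 0.01 * deg * EARTH_RADIUS_M
        dzdx = ((z[0, 2] + 2 * z[1, 2] + z[2, 2])
                - (z[0, 0] + 2 * z[1, 0] + z[2, 0])) / (8 * dx)
        dzdy = ((z[2, 0] + 2 * z[2, 1] + z[2, 2])
                - (z[0, 0] + 2 * z[0, 1] + z[0, 2])) / (8 * dy)
        expected = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        out = horn_slope(RasterLayer(grid, z))
        assert out.values[1, 1] == pytest.approx(expected, rel=1e-12)

    def test_slope_within_bounds_and_nodata_propagation(self, rng):
        vals = rng.normal(-500, 100, size=(10, 10))
        vals[4, 4] = np.nan
        out = horn_slope(layer_from(vals, cell=0.05))
        ok = ~out.nodata
        assert ((out.values[ok] >= 0) & (out.values[ok] < 90)).all()
        # every neighbor of the nodata cell becomes nodata
        assert out.nodata[3:6, 3:6].all()

    def test_too_small_raster(self):
        with pytest.raises(RasterError):
            horn_slope(layer_from(np.zeros((2, 5))))


class TestCellArea:
    def test_equal_along_rows_decreasing_with_latitude(self):
        grid = GridSpec(0.0, 0.0, 0.5, 80, 4)
        area = cell_area(grid)
        assert np.allclose(area.values, area.values[:, :1])
        col = area.values[:, 0]  # row 0 = northernmost
        assert (np.diff(col) > 0).all()

    def test_matches_quadrature(self):
        # 0.041 deg cell centered at 38N vs numerical integration of the
        # spherical area element
        grid = GridSpec(10.0, 38.0, 0.041, 1, 1)
        area = cell_area(grid)
        deg = np.pi / 180
        integral, _ = quad(lambda p: np.cos(p * deg) * deg,
                           38.0 - 0.0205, 38.0 + 0.0205)
        expected = EARTH_RADIUS_KM ** 2 * (0.041 * deg) * integral
        assert area.values[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_full_zone_closed_form(self):
        # 1x1 deg box from 40N to 41N as 100x100 cells of 0.01 deg
        grid = GridSpec(0.005, 40.005, 0.01, 100, 100)
        total = cell_area(grid).values.sum()
        deg = np.pi / 180
        closed = EARTH_RADIUS_KM ** 2 * deg * (np.sin(41 * deg) - np.sin(40 * deg))
        assert total == pytest.approx(closed, rel=1e-10)


class TestGeoTiffIO:
    def test_round_trip_values_mask_and_grid(self, tmp_path, rng):
        vals = rng.normal(size=(12, 9)).astype(np.float32).astype(float)
        mask = rng.random((12, 9)) < 0.2
        vals[mask] = np.nan
        grid = GridSpec(3.25, 41.5, 0.041, 12, 9)
        layer = RasterLayer(grid, vals, mask, name="bathy", units="m")
        path = tmp_path / "x.tif"
        write_raster(layer, path)
        back = read_raster(path, name="bathy", units="m")
        assert np.allclose([back.grid.lon_min, back.grid.lat_min,
                            back.grid.cell_size],
                           [grid.lon_min, grid.lat_min, grid.cell_size])
        assert back.grid.shape == grid.shape
        assert np.array_equal(back.nodata, mask)
        assert np.array_equal(back.values[~mask], vals[~mask])

    def test_nodata_sentinel_masked(self, tmp_path):
        vals = np.array([[1.0, -9999.0], [2.0, 3.0]], dtype=np.float32)
        import tifffile
        path = tmp_path / "s.tif"
        # write via the package to get geo tags, then verify sentinel masking
        grid = GridSpec(0.0, 0.0, 1.0, 2, 2)
        write_raster(RasterLayer(grid, vals.astype(float)), path)
        # -9999 round-trips to nodata because it equals the declared sentinel
        back = read_raster(path)
        assert back.nodata[0, 1] and not back.nodata[0, 0]

    def test_multiband_rejected(self, tmp_path):
        import tifffile
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((4, 4, 3), dtype=np.float32),
                         photometric="rgb")
        with pytest.raises(RasterError, match="band"):
            read_raster(path)

    def test_projected_crs_rejected(self, tmp_path):
        import tifffile
        geokeys = (1, 1, 0, 1, 1024, 0, 1, 1)  # ModelTypeProjected
        path = tmp_path / "proj.tif"
        tifffile.imwrite(path, np.zeros((4, 4), dtype=np.float32), extratags=[
            (33550, "d", 3, (10.0, 10.0, 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, 500000.0, 4000000.0, 0.0)),
            (34735, "H", len(geokeys), geokeys),
        ])
        with pytest.raises(RasterError, match="[Pp]rojected"):
            read_raster(path)
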