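"""Calibration ratio, algorithm disagreement, ordinary kriging, agreement map."""

import numpy as np
import pandas as pd
import pytest

from refugia_sdm import GridSpec
from refugia_sdm.ensemble import ModelRun
from refugia_sdm.evaluation import ModelEvaluation
from refugia_sdm.raster_core import RasterLayer, RasterError, cell_area
from refugia_sdm.uncertainty import (AGREEMENT_CODES, DISAGREEMENT_CODES,
                                     UncertaintyError, VariogramModel,
                                     algorithm_disagreement,
                                     calibration_uncertainty,
                                     disagreement_classes, fit_variogram,
                                     krige_occurrence, kriging_weights,
                                     observation_agreement)


def make_run(run_id, grid, present, algorithm="gam"):
    vals = np.asarray(present, float)
    ev = ModelEvaluation(auc=0.8, tss=0.5, sensitivity=0.8, specificity=0.7,
                         threshold=0.5)
    layer = RasterLayer(grid, vals, ~np.isfinite(vals))
    return ModelRun(run_id=run_id, algorithm=algorithm, repeat_id=1, fold_id=1,
                    evaluation=ev, present_binary=layer, future_binary=layer)


class TestCalibrationUncertainty:
    grid = GridSpec(0, 0, 1.0, 1, 1)

    def test_unanimous_agreement_is_nodata(self):
        runs = [make_run(i, self.grid, [[1.0]]) for i in range(3)]
        out = calibration_uncertainty(runs, "present")
        assert out.nodata[0, 0]

    def test_half_half_ratio_one(self):
        runs = [make_run(i, self.grid, [[v]]) for i, v in
                enumerate([1.0, 1.0, 0.0, 0.0])]
        out = calibration_uncertainty(runs, "present")
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        # {1,1,0,0,1}: mean 0.6, population sd sqrt(0.24), ratio 1.2247...
        runs = [make_run(i, self.grid, [[v]]) for i, v in
                enumerate([1.0, 1.0, 0.0, 0.0, 1.0])]
        out = calibration_uncertainty(runs, "present")
        assert out.values[0, 0] == pytest.approx(0.6 / np.sqrt(0.24), rel=1e-12)

    def test_needs_two_runs(self):
        with pytest.raises(UncertaintyError):
            calibration_uncertainty([make_run(0, self.grid, [[1.0]])], "present")

    def test_ratio_nonnegative_everywhere(self, rng):
        grid = GridSpec(0, 0, 1.0, 4, 4)
        runs = [make_run(i, grid, rng.integers(0, 2, (4, 4)).astype(float))
                for i in range(7)]
        out = calibration_uncertainty(runs, "present")
        assert (out.values[~out.nodata] >= 0).all()


class TestAlgorithmDisagreement:
    grid = GridSpec(0.5, 0.5, 1.0, 1, 4)

    def _dataset(self):
        return pd.DataFrame({"lon": self.grid.lon_centers, "lat": [0.5] * 4,
                             "detected": [1, 1, 0, 0],
                             "row": [0] * 4, "col": np.arange(4)})

    def test_identical_subensembles_agree_everywhere(self):
        pattern = [[1.0, 1.0, 0.0, 0.0]]
        runs = [make_run(0, self.grid, pattern, "gam"),
                make_run(1, self.grid, pattern, "rf")]
        out = algorithm_disagreement(runs, self._dataset(), "present")
        vals = out.values[~out.nodata]
        assert set(vals) <= {DISAGREEMENT_CODES["both_suitable"],
                             DISAGREEMENT_CODES["both_unsuitable"]}

    def test_complementary_binary_maps_never_agree(self):
        g = RasterLayer(self.grid, np.array([[1.0, 1.0, 0.0, 0.0]]))
        r = RasterLayer(self.grid, np.array([[0.0, 0.0, 1.0, 1.0]]))
        out = disagreement_classes(g, r)
        vals = out.values[~out.nodata]
        assert not np.isin(vals, [DISAGREEMENT_CODES["both_suitable"],
                                  DISAGREEMENT_CODES["both_unsuitable"]]).any()

    def test_missing_algorithm_errors(self):
        runs = [make_run(0, self.grid, [[1.0, 1.0, 0.0, 0.0]], "gam")]
        with pytest.raises(UncertaintyError):
            algorithm_disagreement(runs, self._dataset(), "present")


class TestKriging:
    grid = GridSpec(0.0, 0.0, 0.05, 21, 21)

    def _records(self, lons, lats, vals):
        return pd.DataFrame({"lon": lons, "lat": lats, "detected": vals,
                             "source": "survey"})

    def test_constant_observations_reproduced(self):
        rec = self._records([0.1, 0.5, 0.9, 0.3], [0.2, 0.8, 0.4, 0.6],
                            [0.7, 0.7, 0.7, 0.7])
        vgm = VariogramModel("spherical", nugget=0.0, sill=0.2, range_km=50)
        out = krige_occurrence(rec, vgm, self.grid, buffer_km=100)
        assert np.allclose(out.values[~out.nodata], 0.7, atol=1e-8)

    def test_exact_interpolation_with_zero_nugget(self):
        lons, lats = [0.1, 0.5, 0.9], [0.2, 0.8, 0.4]
        rec = self._records(lons, lats, [1.0, 0.0, 1.0])
        vgm = VariogramModel("spherical", nugget=0.0, sill=0.3, range_km=60)
        out = krige_occurrence(rec, vgm, self.grid, buffer_km=200)
        r, c = self.grid.cell_of(np.array(lons), np.array(lats))
        # grid centers don't coincide with stations; predict at the stations
        w = kriging_weights(lons, lats, [1.0, 0.0, 1.0], vgm, lons, lats)
        pred = w @ np.array([1.0, 0.0, 1.0])
        assert np.allclose(pred, [1.0, 0.0, 1.0], atol=1e-6)

    def test_three_point_system_matches_hand_solved_linear_system(self):
        lons = np.array([0.0, 0.4, 0.2])
        lats = np.array([0.0, 0.0, 0.3])
        vals = np.array([1.0, 0.0, 1.0])
        vgm = VariogramModel("spherical", nugget=0.05, sill=0.3, range_km=80)
        target = (0.15, 0.1)
        # independent solve of the 4x4 ordinary-kriging system
        from refugia_sdm.spatial_cv import great_circle_km
        A = np.ones((4, 4))
        A[3, 3] = 0.0
        for i in range(3):
            for j in range(3):
                A[i, j] = vgm(great_circle_km(lons[i], lats[i], lons[j], lats[j]))
        b = np.append([vgm(great_circle_km(lons[i], lats[i], *target))
                       for i in range(3)], 1.0)
        w_expected = np.linalg.solve(A, b)[:3]
        w = kriging_weights(lons, lats, vals, vgm, [target[0]], [target[1]])[0]
        assert np.allclose(w, w_expected, atol=1e-7)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_sum_to_one_everywhere(self, rng):
        lons = rng.uniform(0, 1, 8)
        lats = rng.uniform(0, 1, 8)
        vals = rng.integers(0, 2, 8).astype(float)
        vgm = VariogramModel("exponential", nugget=0.02, sill=0.25, range_km=40)
        w = kriging_weights(lons, lats, vals, vgm,
                            rng.uniform(0, 1, 20), rng.uniform(0, 1, 20))
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-8)

    def test_buffer_masks_distant_cells(self):
        rec = self._records([0.1, 0.15, 0.2], [0.1, 0.15, 0.2], [1.0, 0.0, 1.0])
        vgm = VariogramModel("spherical", nugget=0.0, sill=0.3, range_km=60)
        out = krige_occurrence(rec, vgm, self.grid, buffer_km=10)
        from refugia_sdm.spatial_cv import great_circle_km
        lon_g, lat_g = np.meshgrid(self.grid.lon_centers, self.grid.lat_centers)
        d = np.min(np.stack([great_circle_km(lon_g, lat_g, lo, la)
                             for lo, la in zip(rec["lon"], rec["lat"])]), axis=0)
        assert (out.nodata == (d > 10)).all()

    def test_duplicate_points_averaged(self):
        rec = self._records([0.1, 0.1, 0.5, 0.9], [0.2, 0.2, 0.8, 0.4],
                            [1.0, 0.0, 1.0, 0.0])
        vgm = VariogramModel("spherical", nugget=0.0, sill=0.3, range_km=60)
        out = krige_occurrence(rec, vgm, self.grid, buffer_km=200)
        assert out.n_valid > 0  # singular system avoided by averaging

    def test_pseudo_absences_rejected(self):
        rec = self._records([0.1, 0.5, 0.9], [0.2, 0.8, 0.4], [1, 0, 1])
        rec.loc[0, "source"] = "pseudo_absence"
        vgm = VariogramModel()
        with pytest.raises(UncertaintyError):
            krige_occurrence(rec, vgm, self.grid)

    def test_variogram_fit_recovers_plausible_model(self, raw_records):
        sv = raw_records[raw_records["source"] == "survey"].iloc[:400]
        vgm = fit_variogram(sv["lon"], sv["lat"], sv["detected"].to_numpy(float))
        assert vgm.sill > 0 and vgm.range_km > 0 and vgm.nugget >= 0


class TestObservationAgreement:
    grid = GridSpec(0, 0, 1.0, 2, 2)

    def test_truth_table_exhaustive(self):
        model = RasterLayer(self.grid, np.array([[1.0, 1.0], [0.0, 0.0]]))
        kriged = RasterLayer(self.grid, np.array([[0.9, 0.1], [0.1, 0.9]]))
        out = observation_agreement(model, kriged, occ_threshold=0.5)
        assert out.values[0, 0] == AGREEMENT_CODES["agreement_suitable"]
        assert out.values[0, 1] == AGREEMENT_CODES["disagreement_suitable"]
        assert out.values[1, 0] == AGREEMENT_CODES["agreement_unsuitable"]
        assert out.values[1, 1] == AGREEMENT_CODES["disagreement_unsuitable"]

    def test_identical_maps_no_disagreement(self):
        vals = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = RasterLayer(self.grid, vals)
        out = observation_agreement(model, RasterLayer(self.grid, vals))
        codes = set(out.values.ravel())
        assert AGREEMENT_CODES["disagreement_suitable"] not in codes
        assert AGREEMENT_CODES["disagreement_unsuitable"] not in codes

    def test_unsurveyed_outside_footprint(self):
        model = RasterLayer(self.grid, np.ones((2, 2)))
        kvals = np.array([[0.9, np.nan], [np.nan, np.nan]])
        out = observation_agreement(model, RasterLayer(self.grid, kvals))
        assert out.values[0, 0] == AGREEMENT_CODES["agreement_suitable"]
        assert out.values[1, 1] == AGREEMENT_CODES["unsurveyed"]

    def test_class_areas_sum_to_surveyed_footprint(self):
        grid = GridSpec(0, 40, 0.5, 6, 6)
        rng = np.random.default_rng(5)
        model = RasterLayer(grid, rng.integers(0, 2, (6, 6)).astype(float))
        kvals = rng.random((6, 6))
        kvals[rng.random((6, 6)) < 0.3] = np.nan
        kriged = RasterLayer(grid, kvals)
        out = observation_agreement(model, kriged)
        area = cell_area(grid).values
        surveyed = np.isfinite(kvals)
        surveyed_classes = [AGREEMENT_CODES[k] for k in
                            ("agreement_suitable", "disagreement_suitable",
                             "agreement_unsuitable", "disagreement_unsuitable")]
        class_area = sum(area[out.values == c].sum() for c in surveyed_classes)
        assert class_area == pytest.approx(area[surveyed].sum())

    def test_grid_mismatch(self):
        model = RasterLayer(self.grid, np.ones((2, 2)))
        other = RasterLayer(GridSpec(0, 0, 0.5, 2, 2), np.ones((2, 2)))
        with pytest.raises(RasterError):
            observation_agreement(model, other)
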