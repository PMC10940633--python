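import numpy as np
import pandas as pd
import pytest

from refugia_sdm import (GridSpec, SurveyDesign, TruthParams, generate_seascape,
                         sample_occurrences)
from refugia_sdm.data_prep import (add_pseudo_absences, aggregate_to_grid,
                                   extract_predictors)
from refugia_sdm.pipeline import PipelineConfig
from refugia_sdm.synthetic_seascape import PREDICTOR_NAMES


@pytest.fixture(scope="session")
def basin_grid():
    """~1000 km x 1000 km basin at 0.15 deg resolution."""
    return GridSpec(lon_min=10.0, lat_min=34.0, cell_size=0.15,
                    n_rows=60, n_cols=60)


@pytest.fixture(scope="session")
def seascape(basin_grid):
    return generate_seascape(basin_grid, TruthParams(), seed=7)


@pytest.fixture(scope="session")
def po_boxes(basin_grid):
    return PipelineConfig(seed=0).presence_only_regions


@pytest.fixture(scope="session")
def raw_records(seascape, po_boxes):
    design = SurveyDesign(n_survey_stations=800, presence_only_regions=po_boxes,
                          n_presence_only=40, seed=11)
    return sample_occurrences(seascape["truth"],
                              seascape["present"]["bathymetry"], design)


@pytest.fixture(scope="session")
def model_dataset(seascape, raw_records, po_boxes, basin_grid):
    """Fully prepared model table: pseudo-absences, aggregation, predictors."""
    bathy = seascape["present"]["bathymetry"]
    with_pa = add_pseudo_absences(raw_records, po_boxes, bathy, seed=5)
    agg = aggregate_to_grid(with_pa, basin_grid, seed=6)
    return extract_predictors(agg, seascape["present"])


@pytest.fixture(scope="session")
def predictor_names():
    return list(PREDICTOR_NAMES)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
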