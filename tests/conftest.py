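import numpy as np
import pytest

import orangsim as osm
from orangsim.synthetic_landscape import PREDICTOR_NAMES


@pytest.fixture(scope="session")
def landscape_truth():
    cfg = osm.SyntheticConfig(grid_shape=(32, 32), seed=7)
    return osm.generate_landscape(cfg)


@pytest.fixture(scope="session")
def landscape(landscape_truth):
    return landscape_truth[0]


@pytest.fixture(scope="session")
def truth(landscape_truth):
    return landscape_truth[1]


@pytest.fixture(scope="session")
def gridded(landscape_truth):
    """Gridded modelling dataset with pseudoabsences on the 32x32 landscape."""
    landscape, truth = landscape_truth
    survey = osm.generate_survey(landscape, truth, transect_spacing=2.5,
                                 repeat_years=[2001, 2002, 2007, 2009],
                                 reserve_bias=0.5, seed=8)
    pa = osm.sample_pseudoabsences(
        landscape, 80, seed=9,
        surveyed=survey.records[["row", "col"]].drop_duplicates())
    return osm.aggregate_counts(osm.NestSurvey(survey.records, pa), landscape)


@pytest.fixture(scope="session")
def small_fit_config():
    return osm.HurdleFitConfig(lr_grid=(0.01,), tc_grid=(2,),
                               nt_grid=tuple(range(10, 511, 25)),
                               cv_folds=5, seed=3)


@pytest.fixture(scope="session")
def fitted_model(gridded, small_fit_config):
    """A cheap fitted hurdle model shared across tests."""
    return osm.optimize_hurdle(gridded, list(PREDICTOR_NAMES), small_fit_config)


@pytest.fixture(scope="session")
def vulnerability(landscape):
    rng = np.random.default_rng(21)
    k = len(landscape.classes)
    proba = rng.dirichlet(np.ones(k), size=landscape.landcover.size)
    return osm.vulnerability_from_probabilities(proba, landscape.landcover)
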