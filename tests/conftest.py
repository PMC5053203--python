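"""Shared fixtures: one synthetic landscape + census at the study scale.

The reference fixture is a 40 x 40 km grid partitioned into 16
sub-districts with 5000 candidate holders, generated at seed 20161006;
expensive artifacts (landscape, census, zonal frame, fitted models) are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pigscape import hurdle as hd
from pigscape import synthetic as syn
from pigscape.covariates import RESPONSE_NAMES, prepare_predictors, zonal_aggregate

FIXTURE_SEED = 20161006
MODEL_SEED = 7


@pytest.fixture(scope="session")
def landscape():
    cfg = syn.LandscapeConfig(
        grid_rows=40, grid_cols=40, n_subdistricts=16, n_poi=5, random_seed=FIXTURE_SEED
    )
    return syn.generate_landscape(cfg)


@pytest.fixture(scope="session")
def gen_params():
    return syn.default_generative_params()


@pytest.fixture(scope="session")
def census(landscape, gen_params):
    return syn.generate_holders(landscape, gen_params, n_holders=5000, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def predictor_stack(landscape):
    return prepare_predictors(landscape.layers)


@pytest.fixture(scope="session")
def zonal_frame(predictor_stack, landscape, census):
    return zonal_aggregate(predictor_stack, landscape.zone_raster, census.holders)


@pytest.fixture(scope="session")
def hurdle_models(zonal_frame):
    return {r: hd.fit_hurdle(zonal_frame, r, seed=MODEL_SEED) for r in RESPONSE_NAMES}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
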