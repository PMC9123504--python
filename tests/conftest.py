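"""Shared fixtures: packaged synthetic inputs and calibrated models.

Calibration is expensive, so calibrated models are session-scoped and run at
a reduced budget adequate for the property checks that use them.
"""

import numpy as np
import pytest

from prostasim import synthetic_data as syn
from prostasim.calibration import calibrate_all
from prostasim.demographics import extrapolate_lifetable
from prostasim.engine import ModelSpec

SEED = 1


@pytest.fixture(scope="session")
def lifetable():
    return extrapolate_lifetable(syn.make_lifetable(), 94)


@pytest.fixture(scope="session")
def pyramid():
    return syn.make_pyramid()


@pytest.fixture(scope="session")
def targets():
    return syn.make_incidence_targets()


@pytest.fixture(scope="session")
def model_p(lifetable, pyramid):
    return ModelSpec("P", syn.default_nh_params("P"), syn.default_survival_params(), lifetable, pyramid)


@pytest.fixture(scope="session")
def model_f(lifetable, pyramid):
    return ModelSpec("F", syn.default_nh_params("F"), syn.default_survival_params(), lifetable, pyramid)


@pytest.fixture(scope="session")
def calibrated_p(model_p, targets):
    model, reports = calibrate_all(model_p, targets, sim_budget=60_000, seed=SEED)
    return model, reports


@pytest.fixture(scope="session")
def calibrated_f(model_f, targets):
    model, reports = calibrate_all(model_f, targets, sim_budget=60_000, seed=SEED)
    return model, reports
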