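import numpy as np
import pytest
from hypothesis import settings

from caulirheo.creep_model import BurgersParams
from caulirheo.synthetic_data import LoadSchedule, gen_creep_curve

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    """The study's creep schedule: 600 s hold, 600 s recovery, 1-s sampling."""
    return LoadSchedule(hold_s=600.0, recovery_s=600.0, step_s=1.0)


@pytest.fixture(scope="session")
def three_elem_params():
    """A three-element truth with well-separated relaxation times."""
    return BurgersParams(0.010, ((0.020, 5.0), (0.015, 60.0), (0.012, 250.0)), 2e-5)


@pytest.fixture(scope="session")
def one_elem_params():
    return BurgersParams(0.010, ((0.020, 60.0),), 2e-5)


@pytest.fixture(scope="session")
def noiseless_three_elem_curve(three_elem_params, schedule):
    return gen_creep_curve(three_elem_params, schedule, noise_cv=0.0)
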