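import logging

import numpy as np
import pytest

from mbdoe.models import InputSchedule, generate_plant_data, hes1_model

logging.getLogger("mbdoe").setLevel(logging.ERROR)

HES1_TIMES = [0.0, 2.0, 5.0, 8.0, 10.0, 50.0, 100.0, 150.0, 200.0]
INITIAL_POINTS = [("m", 10.0), ("m", 20.0), ("m", 60.0),
                  ("P1+P2", 10.0), ("P1+P2", 20.0), ("P1+P2", 60.0)]


@pytest.fixture(scope="session")
def hes1():
    return hes1_model()


@pytest.fixture(scope="session")
def base_schedule():
    return InputSchedule.constant(HES1_TIMES, 1.0, bounds=[[0.01], [2.0]])


@pytest.fixture(scope="session")
def initial_dataset(hes1, base_schedule):
    return generate_plant_data(hes1, hes1.nominal_unknowns, base_schedule,
                               INITIAL_POINTS, 0.10, 3, seed=42,
                               schedule_id="initial")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
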