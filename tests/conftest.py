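import numpy as np
import pandas as pd
import pytest

from nlrl.choice import ChoiceParams, simulate_choices
from nlrl.environments import gen_magnitude_task, gen_random_env
from nlrl.models import ModelParams


@pytest.fixture(scope="session")
def magnitude_schedule():
    return gen_magnitude_task(seed=42)


@pytest.fixture(scope="session")
def random_schedule():
    return gen_random_env(n_trials=60, n_switches=2, sd=0.1, seed=7)


@pytest.fixture(scope="session")
def rw_choice_records(magnitude_schedule):
    """Choices of a known RW agent on the magnitude task (the MLE oracle)."""
    mp = ModelParams(model_id="RW", eta0=0.3)
    cp = ChoiceParams(rho=1.0, inv_temp=8.0)
    records, trace = simulate_choices(magnitude_schedule, mp, cp, seed=99,
                                      task="magnitude")
    return records, mp, cp
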