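import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=100)
settings.load_profile("ci")

from bexsim import (
    DosingRegimen,
    InitialConditions,
    ModelParameters,
    simulate,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Published simulation parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def ics() -> InitialConditions:
    return InitialConditions()


@pytest.fixture(scope="session")
def untreated_390(params, ics):
    """Full untreated life course, age 2 -> 15 months (shared, read-only)."""
    return simulate(params, ics, DosingRegimen.untreated(), 390.0)


@pytest.fixture(scope="session")
def treated_6mo_14d(params):
    """Six-month-old mouse, 100 mg/kg daily for 14 days (shared, read-only)."""
    from bexsim import run_life_course

    return run_life_course(params, 6.0, DosingRegimen(B0=100.0, L=1.0), 14.0)
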