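import numpy as np
import pytest

from allostasim.params import EvaluationMode, ModelParameters, Schedule


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Packaged reference calibration."""
    from allostasim import reference_parameters

    return reference_parameters()


@pytest.fixture()
def toy_params() -> ModelParameters:
    """Short-horizon ledger for fast engine-level tests."""
    return ModelParameters().replace(
        horizon_days=3,
        availability_start_day=1,
        n_runs=4,
    )


@pytest.fixture()
def toy_schedule(toy_params) -> Schedule:
    return Schedule(availability_windows=[(0, toy_params.horizon_hours)])


@pytest.fixture()
def empty_schedule(toy_params) -> Schedule:
    return Schedule()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
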