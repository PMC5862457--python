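import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rsmkit import (
    ResponseMatrix,
    ScaleDefinition,
    fit_rsm,
    simulate_responses,
    upps_scale_definition,
)
from rsmkit.simulate import SimulationConfig, evenly_spaced_betas


def make_matrix(rows, n_categories=5, person_ids=None, item_ids=None):
    """Small-literal ResponseMatrix builder; None entries become missing."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in rows]
    )
    return ResponseMatrix(
        person_ids=tuple(person_ids or (f"p{i}" for i in range(arr.shape[0]))),
        item_ids=tuple(item_ids or (f"i{j}" for j in range(arr.shape[1]))),
        responses=arr,
        n_categories=n_categories,
    )


@pytest.fixture(scope="session")
def upps_scale():
    return upps_scale_definition()


@pytest.fixture(scope="session")
def recovery_study():
    """The standard known-truth calibration study: 500 persons, 10 items, K=4."""
    config = SimulationConfig(
        n_persons=500,
        item_betas=tuple(evenly_spaced_betas(10)),
        taus=(-1.5, -0.5, 0.5, 1.5),
        seed=42,
    )
    rm, truth = simulate_responses(config)
    return rm, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_study):
    rm, _ = recovery_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_rsm(rm)


@pytest.fixture(scope="session")
def recovery_fit_corrected(recovery_study):
    rm, _ = recovery_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_rsm(rm, bias_correction=True)


@pytest.fixture(scope="session")
def one_dim_scale():
    """A single 12-item dimension with a 4-item short form."""
    return ScaleDefinition(
        dimensions={"d": [f"i{j + 1}" for j in range(12)]},
        short_form={"d": ["i2", "i5", "i8", "i11"]},
    )
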