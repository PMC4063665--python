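import numpy as np
import pytest

from sidyn import (
    CultureConditions,
    KineticParameters,
    ObservationDesign,
    Objective,
    generate_dataset,
    simulate,
)


@pytest.fixture(scope="session")
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def conditions():
    return CultureConditions()


@pytest.fixture(scope="session")
def default_trajectory(params, conditions):
    return simulate(params, conditions)


@pytest.fixture(scope="session")
def noise_free_dataset(params, conditions):
    return generate_dataset(
        params, conditions, design=ObservationDesign(seed=1, noise_scale=0.0)
    )


@pytest.fixture(scope="session")
def noisy_dataset(params, conditions):
    return generate_dataset(params, conditions, design=ObservationDesign(seed=7))


@pytest.fixture(scope="session")
def noise_free_objective(noise_free_dataset, conditions):
    return Objective(noise_free_dataset, conditions)
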