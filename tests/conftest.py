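import numpy as np
import pytest

from spatcc import (
    CaseControlPattern,
    PopulationCenter,
    StrataSpec,
    StudyWindow,
    SyntheticScenario,
)


@pytest.fixture(scope="session")
def unit_window():
    return StudyWindow.rectangle(0.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def km_window():
    """1 km x 1 km window in meters."""
    return StudyWindow.rectangle(0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_case_control(rng, n_cases, n_controls, window, size=1000.0):
    coords = rng.uniform(0, size, size=(n_cases + n_controls, 2))
    is_case = np.zeros(n_cases + n_controls, dtype=bool)
    is_case[:n_cases] = True
    return CaseControlPattern(coords=coords, is_case=is_case, window=window)


@pytest.fixture()
def small_dataset(rng, km_window):
    """10 cases + 10 controls, uniform over the 1 km window."""
    return random_case_control(rng, 10, 10, km_window)


def null_scenario(n_cases=20, seed=None, window_km=10.0, injected_cluster=None):
    """Small constant-risk scenario: one urban center, coarse strata."""
    size = window_km * 1000.0
    return SyntheticScenario(
        window=StudyWindow.rectangle(0.0, 0.0, size, size),
        population_centers=(
            PopulationCenter((size / 2, size / 2), size / 3.5),
        ),
        n_cases=n_cases,
        seed=seed,
        strata=StrataSpec(birth_year_range=(2000, 2003), region_weights=(("A", 1.0),)),
        injected_cluster=injected_cluster,
    )
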