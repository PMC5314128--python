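"""Shared fixtures: simulated cohorts are expensive, so they are session-scoped."""

from __future__ import annotations

import pytest
from hypothesis import settings

from mphsccs import SimulationConfig, simulate_cases
from mphsccs.scenarios import ScenarioConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort500():
    """Default-configuration cohort of 500 cases."""
    return simulate_cases(SimulationConfig(n_cases_target=500, seed=42))


@pytest.fixture(scope="session")
def cohort1000():
    """Default-configuration cohort of 1000 cases (realism checks)."""
    return simulate_cases(SimulationConfig(n_cases_target=1000, seed=5))


@pytest.fixture(scope="session")
def data500(cohort500):
    return cohort500.to_data()


@pytest.fixture()
def pre90_scenario():
    return ScenarioConfig(name="primary_pre90")
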