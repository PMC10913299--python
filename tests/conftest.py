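"""Shared fixtures: small synthetic cohorts and extraction settings."""

from __future__ import annotations

import numpy as np
import pytest

from startpheno.features import ExtractionConfig
from startpheno.simulate import SimulationConfig, default_profiles, simulate_cohort


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-child cohort (8 per group), fixed seed."""
    return simulate_cohort(SimulationConfig(seed=42, n_per_group=(8, 8, 8)))


@pytest.fixture(scope="session")
def default_cohort():
    """The full 131-child study-sized cohort, fixed seed (shared: slow)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def extraction():
    return ExtractionConfig(pci_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
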