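"""Shared fixtures: synthetic study inputs and a full pipeline run."""

from __future__ import annotations

import pytest
from hypothesis import settings

from mirforge.esv_model import estimate_esv_profile

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mirforge.preprocess import preprocess_reads
from mirforge.synthetic_data import (
    SimulationConfig,
    generate_control_references,
    generate_mirnaome,
    simulate_library,
)

PIPELINE_SEED = 7


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def synthetic_mirnaome(default_config):
    return generate_mirnaome(default_config)


@pytest.fixture(scope="session")
def controls(default_config):
    return generate_control_references(default_config.seed)


@pytest.fixture(scope="session")
def simulated_library(default_config, synthetic_mirnaome, controls):
    """The default 1e5-read library with its truth manifest."""
    return simulate_library(default_config, synthetic_mirnaome, controls)


@pytest.fixture(scope="session")
def collapsed_library(default_config, simulated_library):
    reads, _ = simulated_library
    return preprocess_reads([seq for _, seq, _ in reads], default_config.adapter)


@pytest.fixture(scope="session")
def esv_profile(collapsed_library, controls):
    return estimate_esv_profile(collapsed_library, controls)
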