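"""Shared fixtures: the synthetic multi-temperature fixture and idealized
model-compound geometries for environment classification."""

from __future__ import annotations

import pytest
from hypothesis import settings, HealthCheck

from uriding import generate_fixture
from uriding.reference import (model_compound_cases, structure_from_cartesian,
                               water_molecule)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# aliases kept for the test modules
make_p1_structure = structure_from_cartesian

__all__ = ["make_p1_structure", "model_compound_cases", "water_molecule"]


@pytest.fixture(scope="session")
def default_fixture():
    """The noiseless default fixture (seed 0, 8-temperature grid)."""
    return generate_fixture()
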