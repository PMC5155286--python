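"""Shared fixtures: small and full-size two-sphere inverse problems."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strecg.experiments import build_two_sphere_problem
from strecg.mesh import generate_sphere_mesh

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sphere64():
    """Unit sphere with 64 nodes (fast geometric checks)."""
    return generate_sphere_mesh(1.0, 64)


@pytest.fixture(scope="session")
def small_problem():
    """Reduced two-sphere study: 64 nodes, 10 ms sampling (T = 31)."""
    return build_two_sphere_problem(nodes=64, dt_ms=10.0)


@pytest.fixture(scope="session")
def full_problem():
    """The study-size problem: 184-node spheres, 1 ms sampling (T = 301)."""
    return build_two_sphere_problem(nodes=184, dt_ms=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
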