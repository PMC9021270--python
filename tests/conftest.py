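"""Shared synthetic fixtures for the test suite.

Everything is generated programmatically and seeded; session scope keeps
the expensive objects (connectomes, receptor maps) shared across tests.
"""

import numpy as np
import pytest

import gabadmf as g


@pytest.fixture(scope="session")
def sphere_spec():
    return g.FixtureSpec(n_regions=20, seed=7)


@pytest.fixture(scope="session")
def sphere_connectome(sphere_spec):
    return g.synth_connectome(sphere_spec)


@pytest.fixture(scope="session")
def sphere_map(sphere_spec, sphere_connectome):
    return g.synth_receptor_map(sphere_spec, sphere_connectome.coordinates)


@pytest.fixture(scope="session")
def scaled_sphere(sphere_connectome):
    return g.scale_for_simulation(sphere_connectome)


@pytest.fixture(scope="session")
def tiny_config():
    """Short-scan configuration for fast end-to-end chain tests."""
    return g.SimulationConfig(dt_ms=0.25, n_TRs=40, burn_in_s=5.0)


@pytest.fixture(scope="session")
def tuned_sphere_model(sphere_connectome, tiny_config):
    """A calibrated (FIC-tuned) model on the 20-region sphere fixture."""
    return g.assemble_model(sphere_connectome, G=1.2, config=tiny_config, seed=1)


def random_bold(n_regions=5, n_TRs=60, TR=2.0, seed=0):
    rng = np.random.default_rng(seed)
    sig = rng.standard_normal((n_regions, n_TRs))
    labels = tuple(f"R{i:03d}" for i in range(n_regions))
    return g.BOLDTimeseries(signal=sig, TR=TR, labels=labels)
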