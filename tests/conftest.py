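"""Shared fixtures: phantoms and (expensive) segmentation runs."""

from __future__ import annotations

import numpy as np
import pytest

import mgdfseg
from mgdfseg import RunConfig
from mgdfseg.level_set import initialize_from_vesselness
from mgdfseg.phantoms import default_phantom, two_phase_fixture


@pytest.fixture(scope="session")
def phantom_std3():
    """Default three-tube phantom, noise std 3, fixed seed."""
    return default_phantom(noise_std=3.0, seed=1)


@pytest.fixture(scope="session")
def lp_std3(phantom_std3):
    return mgdfseg.enhance(phantom_std3.image)


@pytest.fixture(scope="session")
def mgdf_run_std3(phantom_std3, lp_std3):
    """Full MGDF segmentation of the std-3 phantom, vesselness-guided init."""
    phi0 = initialize_from_vesselness(lp_std3)
    return mgdfseg.evolve(phantom_std3.image, lp_std3, RunConfig(), phi0=phi0)


@pytest.fixture(scope="session")
def disk_pair():
    """Two-phase disk fixture: values 100/20, radius 16 on 64x64, noise 3."""
    return two_phase_fixture((64, 64), 100.0, 20.0, radius=16.0, noise_std=3.0, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
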