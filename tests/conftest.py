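"""Shared fixtures: the default-scale model is built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from v1ssn.connectivity import ConnectivityParams, build_weights
from v1ssn.geometry import GridSpec, make_orientation_map
from v1ssn.protocols import make_fixture

#: map seed used for all full-scale session fixtures
SESSION_MAP_SEED = 11


@pytest.fixture(scope="session")
def default_map():
    return make_orientation_map(seed=SESSION_MAP_SEED)


@pytest.fixture(scope="session")
def default_weights(default_map):
    return build_weights(default_map)


@pytest.fixture(scope="session")
def small_bundle():
    """24x24 miniature model with full-model degrees-per-cell calibration."""
    return make_fixture("small", seed=2)


@pytest.fixture(scope="session")
def tiny_map():
    """6x6 map for exhaustive / oracle tests."""
    grid = GridSpec(n_side=6, field_of_view=16.0 * 6 / 75.0)
    return make_orientation_map(grid, seed=3)


@pytest.fixture(scope="session")
def tiny_dense_weights(tiny_map):
    return build_weights(tiny_map, ConnectivityParams(), mode="dense")
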