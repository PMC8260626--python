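"""Shared fixtures: small grids and libraries, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from chemsteg.chemchannel import (
    ExtractModel,
    SubstrateModel,
    simulate_extracts,
    simulate_substrate,
)
from chemsteg.geometry import GridGeometry

API_KEY = "fa763032-6efb-4189-b626-9029686537b3"


@pytest.fixture(scope="session")
def small_geometry() -> GridGeometry:
    return GridGeometry(rows=8, cols=8)


@pytest.fixture(scope="session")
def substrate_model() -> SubstrateModel:
    return SubstrateModel()


@pytest.fixture(scope="session")
def extract_model(substrate_model) -> ExtractModel:
    return ExtractModel(substrate=substrate_model)


@pytest.fixture(scope="session")
def small_grid(small_geometry, substrate_model):
    """An untreated 8x8 substrate grid, default catalog."""
    return simulate_substrate(1234, small_geometry, substrate_model)


@pytest.fixture(scope="session")
def library(extract_model):
    """Three near-identical extracts over the default substrate."""
    return simulate_extracts(99, 3, extract_model)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
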