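"""Shared fixtures: the default phantom assembly is expensive (~10 s), so it
is built once per session and reused by measurement and acceptance tests."""

import numpy as np
import pytest

from labyrinthometry import (
    PhantomSpec,
    assemble_labyrinth,
    extract_voxel_cloud,
    fit_plane,
)

CANAL_NAMES = ("LSC", "PSC", "SSC")


@pytest.fixture(scope="session")
def default_assembly():
    """(LabelVolume, GroundTruth) for the default phantom, canonical pose."""
    return assemble_labyrinth(PhantomSpec())


@pytest.fixture(scope="session")
def default_clouds(default_assembly):
    vol, _ = default_assembly
    return {name: extract_voxel_cloud(vol, name) for name in vol.label_map}


@pytest.fixture(scope="session")
def canal_fits(default_clouds):
    return {n: fit_plane(default_clouds[n].points_mm) for n in CANAL_NAMES}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
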